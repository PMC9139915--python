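"""The radiomic feature registry.

The default registry names exactly 143 features drawn from the standard
IBSI families: morphology (18), local intensity peaks (2), total lesion
glycolysis (1), first-order SUV statistics (22), intensity histogram (25),
intensity-volume histogram (12), GLCM (26), GLRLM (16), GLSZM (16) and
NGTDM (5).  The exact composition is an editable manifest — users can load a
JSON manifest to extract a different subset — but the packaged default pins
the 143-feature panel the rest of the pipeline assumes.

Five features form the *conventional* PET subset used by the redundancy
filter: metabolic volume, SUVmax, SUVpeak, SUVmean and TLG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["FeatureRegistry", "default_registry", "CONVENTIONAL_FEATURES"]

#: Conventional PET measures: volume, SUVmax, SUVpeak, SUVmean, TLG.
CONVENTIONAL_FEATURES: tuple[str, ...] = (
    "morph_volume",
    "stat_max",
    "intensity_peak_global",
    "stat_mean",
    "tlg",
)

_MORPH = [
    "morph_volume",
    "morph_surface_area",
    "morph_surface_to_volume_ratio",
    "morph_sphericity",
    "morph_compactness1",
    "morph_compactness2",
    "morph_spherical_disproportion",
    "morph_asphericity",
    "morph_max_diameter_3d",
    "morph_major_axis_length",
    "morph_minor_axis_length",
    "morph_least_axis_length",
    "morph_elongation",
    "morph_flatness",
    "morph_volume_density_aabb",
    "morph_area_density_aabb",
    "morph_volume_density_aee",
    "morph_area_density_aee",
]
_LOCAL = ["intensity_peak_local", "intensity_peak_global"]
_STAT = [
    "stat_mean",
    "stat_variance",
    "stat_skewness",
    "stat_kurtosis",
    "stat_median",
    "stat_min",
    "stat_p5",
    "stat_p10",
    "stat_p25",
    "stat_p75",
    "stat_p90",
    "stat_p95",
    "stat_max",
    "stat_iqr",
    "stat_range",
    "stat_mad",
    "stat_rmad",
    "stat_medad",
    "stat_cov",
    "stat_qcod",
    "stat_energy",
    "stat_rms",
]
_IH = [
    "ih_mean",
    "ih_variance",
    "ih_skewness",
    "ih_kurtosis",
    "ih_median",
    "ih_min",
    "ih_p10",
    "ih_p25",
    "ih_p75",
    "ih_p90",
    "ih_max",
    "ih_mode",
    "ih_iqr",
    "ih_range",
    "ih_mad",
    "ih_rmad",
    "ih_medad",
    "ih_cov",
    "ih_qcod",
    "ih_entropy",
    "ih_uniformity",
    "ih_max_gradient",
    "ih_max_gradient_level",
    "ih_min_gradient",
    "ih_min_gradient_level",
]
_IVH = [
    "ivh_v10",
    "ivh_v25",
    "ivh_v75",
    "ivh_v90",
    "ivh_i10",
    "ivh_i25",
    "ivh_i75",
    "ivh_i90",
    "ivh_v10_minus_v90",
    "ivh_v25_minus_v75",
    "ivh_i10_minus_i90",
    "ivh_i25_minus_i75",
]
_GLCM = [
    "glcm_joint_max",
    "glcm_joint_average",
    "glcm_joint_variance",
    "glcm_joint_entropy",
    "glcm_diff_average",
    "glcm_diff_variance",
    "glcm_diff_entropy",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_asm",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_inverse_difference",
    "glcm_inverse_difference_norm",
    "glcm_inverse_difference_moment",
    "glcm_inverse_difference_moment_norm",
    "glcm_inverse_variance",
    "glcm_correlation",
    "glcm_autocorrelation",
    "glcm_cluster_tendency",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_info_corr1",
    "glcm_info_corr2",
    "glcm_mcc",
]
_GLRLM = [
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_low_gl_emphasis",
    "glrlm_high_gl_emphasis",
    "glrlm_short_run_low_gl_emphasis",
    "glrlm_short_run_high_gl_emphasis",
    "glrlm_long_run_low_gl_emphasis",
    "glrlm_long_run_high_gl_emphasis",
    "glrlm_gl_nonuniformity",
    "glrlm_gl_nonuniformity_norm",
    "glrlm_run_nonuniformity",
    "glrlm_run_nonuniformity_norm",
    "glrlm_run_percentage",
    "glrlm_gl_variance",
    "glrlm_run_variance",
    "glrlm_run_entropy",
]
_GLSZM = [
    "glszm_short_zone_emphasis",
    "glszm_long_zone_emphasis",
    "glszm_low_gl_emphasis",
    "glszm_high_gl_emphasis",
    "glszm_short_zone_low_gl_emphasis",
    "glszm_short_zone_high_gl_emphasis",
    "glszm_long_zone_low_gl_emphasis",
    "glszm_long_zone_high_gl_emphasis",
    "glszm_gl_nonuniformity",
    "glszm_gl_nonuniformity_norm",
    "glszm_zone_nonuniformity",
    "glszm_zone_nonuniformity_norm",
    "glszm_zone_percentage",
    "glszm_gl_variance",
    "glszm_zone_variance",
    "glszm_zone_entropy",
]
_NGTDM = [
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
]

_FAMILIES: dict[str, list[str]] = {
    "morphology": _MORPH,
    "local_intensity": _LOCAL,
    "conventional_composite": ["tlg"],
    "statistics": _STAT,
    "intensity_histogram": _IH,
    "intensity_volume_histogram": _IVH,
    "glcm": _GLCM,
    "glrlm": _GLRLM,
    "glszm": _GLSZM,
    "ngtdm": _NGTDM,
}


@dataclass
class FeatureRegistry:
    """Ordered manifest of (feature name, family) pairs."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in registry: {dupes}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def families(self) -> set[str]:
        return {f for _, f in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in set(self.names)

    def subset(self, names) -> "FeatureRegistry":
        wanted = set(names)
        return FeatureRegistry([(n, f) for n, f in self.entries if n in wanted])

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps([{"name": n, "family": f} for n, f in self.entries], indent=1)
        )

    @classmethod
    def from_json(cls, path) -> "FeatureRegistry":
        raw = json.loads(Path(path).read_text())
        return cls([(e["name"], e["family"]) for e in raw])


def default_registry() -> FeatureRegistry:
    """The packaged 143-feature panel."""
    entries = [(name, fam) for fam, names in _FAMILIES.items() for name in names]
    reg = FeatureRegistry(entries)
    assert len(reg) == 143, f"default registry must have 143 features, has {len(reg)}"
    return reg
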