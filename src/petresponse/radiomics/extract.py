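"""Full-registry feature extraction for single VOIs and whole cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..pet_io import SUVImage, VOIMask, resample_to_isotropic
from . import features as F
from .registry import FeatureRegistry, default_registry
from .texture import discretize, glcm_merged, glrlm_merged, glszm, ngtdm

__all__ = ["extract_all", "extract_cohort"]

_FAMILY_ORDER = (
    "morphology",
    "local_intensity",
    "conventional_composite",
    "statistics",
    "intensity_histogram",
    "intensity_volume_histogram",
    "glcm",
    "glrlm",
    "glszm",
    "ngtdm",
)


def extract_all(
    image: SUVImage,
    mask: VOIMask,
    registry: FeatureRegistry | None = None,
    bin_width: float = 0.25,
) -> pd.Series:
    """Compute every registry feature for one resampled image/mask pair.

    Returns a Series indexed by feature name, in registry order; all values
    are finite and the computation is deterministic.  Errors inside a feature
    family are re-raised with the family attached.
    """
    registry = registry or default_registry()
    mask.check_paired(image)
    values: dict[str, float] = {}
    needed = registry.families

    def _run(family: str, fn, *args):
        try:
            values.update(fn(*args))
        except ValueError as exc:
            raise ValueError(f"[{family}] {exc}") from exc

    if needed & {"morphology"}:
        _run("morphology", F.morphology_features, mask)
    if needed & {"local_intensity", "conventional_composite", "statistics", "intensity_volume_histogram"}:
        _run("intensity", F.intensity_features, image, mask)
    texture_needed = needed & {"intensity_histogram", "glcm", "glrlm", "glszm", "ngtdm"}
    if texture_needed:
        disc = discretize(image, mask, bin_width=bin_width)
        n_vox = mask.voxel_count
        if "intensity_histogram" in needed:
            _run("intensity_histogram", F.histogram_features, disc, mask)
        if "glcm" in needed:
            _run("glcm", F.glcm_features, glcm_merged(disc, mask))
        if "glrlm" in needed:
            _run("glrlm", F.glrlm_features, glrlm_merged(disc, mask), n_vox)
        if "glszm" in needed:
            _run("glszm", F.glszm_features, glszm(disc, mask), n_vox)
        if "ngtdm" in needed:
            _run("ngtdm", F.ngtdm_features, ngtdm(disc, mask))

    out = pd.Series({name: values[name] for name in registry.names}, dtype=np.float64)
    bad = out.index[~np.isfinite(out.to_numpy())].tolist()
    if bad:
        raise ValueError(f"non-finite feature values for: {bad}")
    return out


def extract_cohort(
    patients,
    registry: FeatureRegistry | None = None,
    bin_width: float = 0.25,
    target_spacing: float = 2.0,
    resample: bool = True,
) -> pd.DataFrame:
    """Resample and extract features for a synthetic (or loaded) cohort.

    Produces the pipeline's FeatureTable: one row per patient with radiomic
    columns in registry order plus ``histology``, ``t_stage``, ``n_stage``
    and the binary non-response ``label``.
    """
    registry = registry or default_registry()
    rows, meta = [], []
    for p in patients:
        img, msk = (
            resample_to_isotropic(p.image, p.mask, target_spacing)
            if resample
            else (p.image, p.mask)
        )
        vec = extract_all(img, msk, registry=registry, bin_width=bin_width)
        vec.name = p.patient_id
        rows.append(vec)
        meta.append(
            {
                "patient_id": p.patient_id,
                "histology": p.histology,
                "t_stage": p.t_stage,
                "n_stage": p.n_stage,
                "label": p.label,
            }
        )
    feats = pd.DataFrame(rows)
    feats.index.name = "patient_id"
    clin = pd.DataFrame(meta).set_index("patient_id")
    return feats.join(clin)
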