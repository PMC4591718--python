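"""Continuous brain-behavior coupling analysis.

For every region pair, each subject's contribution to the pair's Pearson
correlation — the product of the subject's two z-scored volumes — is treated
as a per-subject coupling value.  That coupling vector is rank-correlated
(Spearman) with the behavioral score across subjects, partialling age, IQ and
intracranial volume, so volume covariance can be related to symptom severity
without dichotomizing the sample.  Single-region volume-behavior partial
correlations use the same machinery with the raw volume column in place of
the product.

Multiple comparisons are corrected with Benjamini-Hochberg FDR over pooled
families: all tests involving subcortical volumes (7 single regions + 21
intra-subcortical pairs + 476 subcortico-cortical pairs = 504 for the
bilateral scheme) form one family; the 68 single cortical volumes and the
2278 cortico-cortical pairs are each corrected in their own family.

The sign of a coupling rho indicates how a pair's joint z-score product
co-varies with severity; it cannot be read directly as joint volume increase
or decrease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, SchemaError, ValidationError
from .io import SUBSCALES, CohortTable, VolumeTable
from .roi import intra_subcortical_pairs, subcortico_cortical_pairs, cortico_cortical_pairs
from .stats_core import bh_fdr, partial_spearman_batch, zproduct_pairs, zscore_columns

#: Caveat repeated in every results header.
SIGN_CAVEAT = (
    "note: the sign of a coupling rho reflects how the z-score product tracks "
    "severity and cannot be directly interpreted as joint volume increase or decrease"
)

_FAMILY_SIZES_BILATERAL = {
    "single_subcortical": 7,
    "intra_subcortical": 21,
    "subcortico_cortical": 476,
    "single_cortical": 68,
    "cortico_cortical": 2278,
}
_FAMILY_SIZES_LATERALIZED = {
    "single_subcortical": 14,
    "intra_subcortical": 91,
    "subcortico_cortical": 952,
    "single_cortical": 68,
    "cortico_cortical": 2278,
}


def family_sizes(mode: str) -> dict[str, int]:
    return dict(
        _FAMILY_SIZES_BILATERAL if mode == "bilateral7" else _FAMILY_SIZES_LATERALIZED
    )


@dataclass
class PairAssociation:
    """One region pair's (or single region's) association with a subscale.

    ``q_flag`` is only ever set by a family-level FDR pass, never per-test.
    """

    pair: tuple[str, str | None]
    family: str
    rho: float
    p: float
    subscale: str
    q_flag: bool = False


def _check_alignment(volumes: VolumeTable, cohort: CohortTable) -> None:
    if volumes.subject_ids != cohort.subject_ids:
        raise ValidationError("volume and phenotype tables list different subjects")


def _infer_single_family(volumes: VolumeTable, rois: Sequence[str]) -> str:
    sub = set(volumes.scheme.subcortical_names)
    classes = {("subcortical" if r in sub else "cortical") for r in rois}
    if classes == {"subcortical"}:
        return "single_subcortical"
    if classes == {"cortical"}:
        return "single_cortical"
    raise SchemaError("single-region family must not mix tissue classes")


def _infer_pair_family(volumes: VolumeTable, pairs: Sequence[tuple[str, str]]) -> str:
    sub = set(volumes.scheme.subcortical_names)
    kinds = set()
    for x, y in pairs:
        n_sub = (x in sub) + (y in sub)
        kinds.add(("intra_subcortical", "subcortico_cortical", "cortico_cortical")[2 - n_sub])
    if len(kinds) != 1:
        raise SchemaError(f"pairs span multiple families: {sorted(kinds)}")
    return kinds.pop()


def regional_volume_association(
    volumes: VolumeTable,
    cohort: CohortTable,
    subscale: str = "insistence_on_sameness",
    roi_subset: Sequence[str] | None = None,
) -> list[PairAssociation]:
    """Partial Spearman of each single ROI volume against a subscale score,
    covarying age, IQ and ICV."""
    _check_alignment(volumes, cohort)
    rois = list(roi_subset) if roi_subset is not None else volumes.scheme.subcortical_names
    if not rois:
        raise ValidationError("empty ROI subset")
    family = _infer_single_family(volumes, rois)
    rho, p = partial_spearman_batch(
        cohort.subscale(subscale), volumes.matrix(rois), cohort.covariates()
    )
    return [
        PairAssociation((roi, None), family, float(r), float(pv), subscale)
        for roi, r, pv in zip(rois, rho, p)
    ]


def coupling_association(
    volumes: VolumeTable,
    cohort: CohortTable,
    subscale: str = "insistence_on_sameness",
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[PairAssociation]:
    """Partial Spearman of each pair's per-subject z-product against a
    subscale score, covarying age, IQ and ICV.

    Volumes are z-scored over the whole sample (the continuous analysis is a
    whole-sample decomposition, not a within-group one).
    """
    _check_alignment(volumes, cohort)
    if pairs is None:
        pairs = intra_subcortical_pairs(volumes.scheme)
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("empty pair list")
    family = _infer_pair_family(volumes, pairs)
    cols = sorted({c for pair in pairs for c in pair}, key=volumes.scheme.names.index)
    z = zscore_columns(volumes.data.loc[:, cols])
    products = zproduct_pairs(z, pairs)
    rho, p = partial_spearman_batch(
        cohort.subscale(subscale), products.values, cohort.covariates()
    )
    return [
        PairAssociation((x, y), family, float(r), float(pv), subscale)
        for (x, y), r, pv in zip(pairs, rho, p)
    ]


def assemble_subcortical_family(
    single: list[PairAssociation],
    intra: list[PairAssociation],
    subcort_cort: list[PairAssociation],
    q: float = 0.05,
) -> tuple[list[PairAssociation], float]:
    """One pooled BH-FDR pass over every subcortical-involving test.

    The family pools single subcortical volumes, intra-subcortical coupling
    and subcortico-cortical coupling (504 tests for the bilateral scheme,
    1057 for the lateralized one).  ``q_flag`` is written back onto each
    record; the realized p threshold is returned (data-dependent).
    """
    n_single = len(single)
    if n_single == 7:
        want = (7, 21, 476)
    elif n_single == 14:
        want = (14, 91, 952)
    else:
        raise ValidationError(f"unexpected single-subcortical family size {n_single}")
    got = (len(single), len(intra), len(subcort_cort))
    if got != want:
        raise ValidationError(
            f"incomplete subcortical family: sizes {got}, expected {want}"
        )
    pooled = single + intra + subcort_cort
    reject, threshold = bh_fdr(np.array([a.p for a in pooled]), q)
    for assoc, flag in zip(pooled, reject):
        assoc.q_flag = bool(flag)
    return pooled, threshold


def run_subcortical_analysis(
    volumes: VolumeTable,
    cohort: CohortTable,
    subscale: str = "insistence_on_sameness",
    q: float = 0.05,
) -> tuple[list[PairAssociation], float]:
    """The full pooled subcortical family for one subscale: single volumes,
    intra-subcortical coupling, subcortico-cortical coupling, one FDR pass."""
    scheme = volumes.scheme
    single = regional_volume_association(volumes, cohort, subscale, scheme.subcortical_names)
    intra = coupling_association(volumes, cohort, subscale, intra_subcortical_pairs(scheme))
    subcort = coupling_association(
        volumes, cohort, subscale, subcortico_cortical_pairs(scheme)
    )
    return assemble_subcortical_family(single, intra, subcort, q)


def cortical_analyses(
    volumes: VolumeTable,
    cohort: CohortTable,
    subscale: str = "insistence_on_sameness",
    q: float = 0.05,
) -> dict[str, tuple[list[PairAssociation], float]]:
    """Single-cortical-volume family (68 tests) and cortico-cortical coupling
    family (2278 tests), each with its own FDR pass."""
    scheme = volumes.scheme
    out: dict[str, tuple[list[PairAssociation], float]] = {}
    single = regional_volume_association(volumes, cohort, subscale, scheme.cortical_names)
    reject, thr = bh_fdr(np.array([a.p for a in single]), q)
    for a, flag in zip(single, reject):
        a.q_flag = bool(flag)
    out["single_cortical"] = (single, thr)
    cc = coupling_association(volumes, cohort, subscale, cortico_cortical_pairs(scheme))
    reject, thr = bh_fdr(np.array([a.p for a in cc]), q)
    for a, flag in zip(cc, reject):
        a.q_flag = bool(flag)
    out["cortico_cortical"] = (cc, thr)
    return out


def subscale_specificity_sweep(
    volumes: VolumeTable,
    cohort: CohortTable,
    q: float = 0.05,
    include_cortical: bool = False,
) -> pd.DataFrame:
    """Repeat the pooled subcortical analysis for all five RBS-R subscales.

    Returns a subscale x family table of corrected-hit counts.  A subscale
    whose scores are degenerate (e.g. constant) yields NaN counts for its row
    and does not disturb the other subscales.
    """
    fams = ["single_subcortical", "intra_subcortical", "subcortico_cortical"]
    if include_cortical:
        fams += ["single_cortical", "cortico_cortical"]
    counts = pd.DataFrame(np.nan, index=list(SUBSCALES), columns=fams)
    for subscale in SUBSCALES:
        try:
            pooled, _ = run_subcortical_analysis(volumes, cohort, subscale, q)
            if include_cortical:
                cort = cortical_analyses(volumes, cohort, subscale, q)
                pooled = pooled + cort["single_cortical"][0] + cort["cortico_cortical"][0]
        except DegenerateInputError:
            continue
        for fam in fams:
            counts.loc[subscale, fam] = sum(
                1 for a in pooled if a.family == fam and a.q_flag
            )
    return counts


def associations_to_dataframe(associations: list[PairAssociation]) -> pd.DataFrame:
    """Flatten association records to the results-TSV layout."""
    return pd.DataFrame(
        {
            "family": [a.family for a in associations],
            "subscale": [a.subscale for a in associations],
            "roi_x": [a.pair[0] for a in associations],
            "roi_y": [a.pair[1] if a.pair[1] is not None else "" for a in associations],
            "rho": [a.rho for a in associations],
            "p": [a.p for a in associations],
            "q_flag": [a.q_flag for a in associations],
        }
    )
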