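"""Synthetic cohort generator with planted, scoreable ground truth.

Emulates the statistical structure the analyses assume: a cohort of
adolescent/young-adult subjects with right-skewed RBS-R subscale raw scores
(insistence on sameness 4.81 +- 5.21, the dominant subscale), Gaussian age
(18.39 +- 3.33 years) and full-scale IQ (111.96 +- 14.24), log-normal
intracranial volume, and inter-regional gray-matter volume coupling whose
strength grows with insistence-on-sameness (IS) severity.

Volume model for ROI r, subject i:

    V_ri = mu_r * (ICV_i / mean ICV) * exp(eps_ri)
           + sigma_r * a_r * w_i * f_{c(r), i}
           + slope_r * IS_i                      (direct volume effects only)

with eps_ri ~ N(0, tau_r^2) multiplicative noise (tau_r from the ROI's
coefficient of variation), sigma_r = mu_r * roi_cv, and the IS-dependent
latent loading

    w_i = sqrt(lambda0 + lambda1 * IS_i / max IS).

Coupling enters through shared latent "growth factors": the coupled regions
are partitioned into disjoint components, each component c drawing one
standard-normal factor f_ci per subject, and every member ROI loading on its
component's factor with loading a_r.  All region pairs within a component
are thereby coupled with pairwise effect a_X * a_Y, and pairs across
components are not — so the planted pair set is exactly the within-component
pair list and recovery can be scored pair by pair.  One factor per ROI
(components are disjoint) keeps a pair's z-score product free of
cross-factor interference, which is what makes a strong, calibratable
per-subject coupling signal possible at n = 55.

The multiplicative ICV term makes head size a genuine confounder, so
partialling ICV is testable.  RBS-R subscale raw scores are drawn from gamma
distributions, rounded to non-negative integers; the continuous gamma
parameters are moment-matched so the *rounded* scores hit the target
mean/SD, preserving the right skew that motivates rank-based correlation.

ICV and per-ROI baseline volumes have no published summary statistics for
this design; defaults are physiologically plausible values recorded here and
clearly synthetic.  Coupling effect sizes were frozen after a one-time
calibration run (see scripts/calibrate_effects.py).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .io import (
    SUBSCALES,
    CohortTable,
    VolumeTable,
    write_phenotypes,
    write_volume_table,
)
from .roi import SchemeMode, load_scheme

#: Target moments (mean, SD) of the rounded raw scores, per RBS-R subscale.
SUBSCALE_MOMENTS: dict[str, tuple[float, float]] = {
    "insistence_on_sameness": (4.81, 5.21),
    "stereotyped": (2.15, 2.26),
    "self_injury": (1.13, 1.31),
    "compulsive": (1.55, 1.96),
    "ritualistic": (2.89, 3.04),
}

#: Plausible bilateral-average subcortical gray-matter volumes (mm^3);
#: synthetic defaults, not derived from any published cohort.
_SUBCORTICAL_MEANS = {
    "thalamus": 7200.0,
    "caudate": 3800.0,
    "putamen": 5500.0,
    "pallidum": 1800.0,
    "hippocampus": 4200.0,
    "amygdala": 1700.0,
    "accumbens": 650.0,
}

_CORTICAL_LOBE_MEANS = {
    "temporal": 9000.0,
    "frontal": 11000.0,
    "parietal": 10000.0,
    "occipital": 7000.0,
    "cingulate": 4000.0,
    "insula": 7000.0,
}

#: Default coupling structure: three disjoint cliques of coupled regions.
#: The subcortical members give exactly five planted intra-subcortical
#: pairs; the first two cliques also recruit cortical partners at a weaker
#: loading, emulating widespread subcortico-cortical coupling.
_DEFAULT_CLIQUES: tuple[tuple[str, ...], ...] = (
    (
        "amygdala",
        "pallidum",
        "accumbens",
        "superior_temporal_left",
        "superior_temporal_right",
        "middle_temporal_left",
        "middle_temporal_right",
        "fusiform_left",
        "fusiform_right",
        "inferior_parietal_left",
        "inferior_parietal_right",
        "supramarginal_left",
        "lateral_orbitofrontal_left",
        "insula_left",
        "insula_right",
    ),
    (
        "hippocampus",
        "putamen",
        "superior_parietal_left",
        "superior_parietal_right",
        "postcentral_left",
        "postcentral_right",
        "precuneus_left",
        "precuneus_right",
        "supramarginal_right",
        "paracentral_left",
        "paracentral_right",
        "precentral_left",
        "precentral_right",
        "superior_frontal_left",
    ),
    (
        "thalamus",
        "caudate",
    ),
)

#: Every within-clique pair, name-sorted: the default planted pair list.
DEFAULT_COUPLED_PAIRS: tuple[tuple[str, str], ...] = tuple(
    tuple(sorted((clique[i], clique[j])))
    for clique in _DEFAULT_CLIQUES
    for i in range(len(clique))
    for j in range(i + 1, len(clique))
)

#: Cortical members load at 0.85 (subcortical at the implicit default 1.0);
#: frozen by the one-time calibration run.
DEFAULT_ROI_LOADINGS: tuple[tuple[str, float], ...] = tuple(
    (roi, 0.85)
    for clique in _DEFAULT_CLIQUES
    for roi in clique
    if roi not in _SUBCORTICAL_MEANS
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    ``coupling_base`` (lambda0) sets IS-independent baseline coupling;
    ``coupling_slope`` (lambda1) sets how strongly coupling grows with IS
    (0 = null cohort: coupling present but unrelated to severity).
    ``coupled_pairs`` lists the planted pairs; because coupling enters
    through shared latent factors, the list must be a union of cliques over
    disjoint ROI sets (every pair within a connected component present), and
    each component draws one factor.  ``roi_loadings`` overrides the default
    loading of 1.0 per coupled ROI; a pair's planted effect is the product
    of its two loadings.  ``roi_means`` and ``roi_cvs`` override the
    built-in per-ROI baseline volume and coefficient of variation
    (``roi_cv`` is the scalar default).  ``volume_effect_rois`` maps ROI
    name to a direct linear volume shift per raw IS point (mm^3).
    """

    n_subjects: int = 55
    seed: int = 0
    scheme_mode: SchemeMode = "bilateral7"
    is_mean: float = 4.81
    is_sd: float = 5.21
    age_mean: float = 18.39
    age_sd: float = 3.33
    iq_mean: float = 111.96
    iq_sd: float = 14.24
    icv_mean: float = 1_500_000.0
    icv_cv: float = 0.08
    roi_cv: float = 0.15
    roi_means: tuple[tuple[str, float], ...] = ()
    roi_cvs: tuple[tuple[str, float], ...] = ()
    coupled_pairs: tuple[tuple[str, str], ...] = DEFAULT_COUPLED_PAIRS
    roi_loadings: tuple[tuple[str, float], ...] = DEFAULT_ROI_LOADINGS
    coupling_base: float = 0.05
    coupling_slope: float = 250.0
    volume_effect_rois: tuple[tuple[str, float], ...] = (("thalamus", -100.0),)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted effects plus the realized latent variables of one cohort.

    ``coupled_pairs`` enumerates every within-component pair with its effect
    (product of member loadings); re-deriving ``latent_w`` from the stored IS
    scores and the config reproduces it exactly.
    """

    coupled_pairs: tuple[tuple[str, str, float], ...]
    volume_effect_rois: tuple[tuple[str, float], ...]
    latent_w: np.ndarray          # per-subject IS-dependent loading w_i
    latent_factors: pd.DataFrame  # subjects x components, the f_ci draws
    clip_count: int

    def planted_pairs(self, family_rois: set[str] | None = None) -> set[tuple[str, str]]:
        """Sorted-name pair set, optionally restricted to pairs within
        ``family_rois`` (e.g. the subcortical names)."""
        out = set()
        for x, y, _ in self.coupled_pairs:
            if family_rois is None or (x in family_rois and y in family_rois):
                out.add(tuple(sorted((x, y))))
        return out


def default_roi_means(scheme_mode: SchemeMode = "bilateral7") -> dict[str, float]:
    """Deterministic plausible baseline volume per ROI of the scheme."""
    scheme = load_scheme(scheme_mode)
    means: dict[str, float] = {}
    for roi in scheme.rois:
        if roi.tissue_class == "subcortical":
            stem = roi.name.removesuffix("_left").removesuffix("_right")
            means[roi.name] = _SUBCORTICAL_MEANS[stem]
        else:
            base = _CORTICAL_LOBE_MEANS[roi.lobe_tag]
            # deterministic +-15 % spread so parcels are not identical
            j = scheme.cortical_names.index(roi.name) % 34
            means[roi.name] = base * (0.85 + 0.30 * j / 33.0)
    return means


@lru_cache(maxsize=32)
def _rounded_gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) whose rounded, zero-clipped draw matches the
    target mean/SD.

    Rounding a right-skewed gamma to the integer lattice biases both moments
    (mass in [0, 0.5) collapses onto 0); a short fixed-point iteration on the
    continuous moments removes the bias.  Analytic lattice moments come from
    the gamma CDF, so the adjustment is deterministic.
    """
    if mean <= 0 or sd <= 0:
        raise ConfigError(f"subscale moments must be positive (mean={mean}, sd={sd})")
    mc, sc = mean, sd
    kmax = int(np.ceil(mean + 12 * sd)) + 2
    ks = np.arange(kmax + 1)
    edges = ks + 0.5
    for _ in range(60):
        shape = (mc / sc) ** 2
        scale = sc**2 / mc
        cdf = stats.gamma.cdf(edges, shape, scale=scale)
        pk = np.diff(np.concatenate([[0.0], cdf]))
        pk[-1] += 1.0 - cdf[-1]
        m_d = float(ks @ pk)
        s_d = float(np.sqrt(max(ks**2 @ pk - m_d**2, 1e-12)))
        if abs(m_d - mean) < 1e-9 and abs(s_d - sd) < 1e-9:
            break
        mc = max(mc + (mean - m_d), 1e-6)
        sc = max(sc * sd / s_d, 1e-6)
    if abs(m_d - mean) > 0.01 * mean or abs(s_d - sd) > 0.01 * sd:
        raise ConfigError(
            f"cannot match rounded-gamma moments mean={mean}, sd={sd} "
            f"(reached {m_d:.4f}, {s_d:.4f})"
        )
    return (mc / sc) ** 2, sc**2 / mc


def _draw_subscale(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Right-skewed non-negative integer raw scores at target moments."""
    shape, scale = _rounded_gamma_params(mean, sd)
    x = rng.gamma(shape, scale, size=n)
    return np.clip(np.round(x), 0, None)


def _clique_components(pairs: tuple[tuple[str, str], ...]) -> list[list[str]]:
    """Connected components of the coupled-pair graph, validated as cliques.

    One latent factor serves one component, so a pair is planted exactly
    when both ROIs share a component; a non-clique component would couple
    pairs the config never listed, making the truth file wrong.
    """
    parent: dict[str, str] = {}

    def find(r: str) -> str:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    pair_set = set()
    for x, y in pairs:
        if x == y:
            raise ConfigError(f"self-pair ({x!r}, {x!r}) in coupled_pairs")
        key = tuple(sorted((x, y)))
        if key in pair_set:
            raise ConfigError(f"duplicate coupled pair {key}")
        pair_set.add(key)
        for r in (x, y):
            parent.setdefault(r, r)
        parent[find(x)] = find(y)

    comps: dict[str, list[str]] = {}
    for r in sorted(parent):
        comps.setdefault(find(r), []).append(r)
    for members in comps.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if (members[i], members[j]) not in pair_set:
                    raise ConfigError(
                        "coupled_pairs must be a union of cliques over disjoint "
                        f"ROI sets (shared-factor coupling): pair "
                        f"({members[i]!r}, {members[j]!r}) is implied by its "
                        "component but not listed"
                    )
    return [comps[root] for root in sorted(comps, key=lambda r: comps[r][0])]


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[CohortTable, VolumeTable, SyntheticTruth]:
    """Draw one cohort (phenotypes, volumes) plus its ground truth.

    Fully reproducible from ``config.seed``; every random draw flows from a
    single generator in fixed order.
    """
    scheme = load_scheme(config.scheme_mode)
    names = set(scheme.names)
    components = _clique_components(tuple(config.coupled_pairs))
    coupled_rois = {r for comp in components for r in comp}
    loadings = {r: 1.0 for r in coupled_rois}
    for roi, loading in config.roi_loadings:
        if loading <= 0:
            raise ConfigError(f"loading for {roi!r} must be positive")
        loadings[roi] = loading
    for label, rois in (
        ("coupled", coupled_rois),
        ("loading", {r for r, _ in config.roi_loadings}),
        ("volume-effect", {r for r, _ in config.volume_effect_rois}),
        ("roi_means", {r for r, _ in config.roi_means}),
        ("roi_cvs", {r for r, _ in config.roi_cvs}),
    ):
        unknown = rois - names
        if unknown:
            raise ConfigError(f"{label} ROI(s) not in scheme: {sorted(unknown)}")
    if config.coupling_base < 0 or config.coupling_base + config.coupling_slope < 0:
        raise ConfigError("coupling parameters must keep lambda0 and lambda0+lambda1 >= 0")

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subject_ids = [f"s{i + 1:03d}" for i in range(n)]

    moments = dict(SUBSCALE_MOMENTS)
    moments["insistence_on_sameness"] = (config.is_mean, config.is_sd)
    scores = {name: _draw_subscale(rng, *moments[name], n) for name in SUBSCALES}
    is_scores = scores["insistence_on_sameness"]

    age = rng.normal(config.age_mean, config.age_sd, n)
    iq = rng.normal(config.iq_mean, config.iq_sd, n)
    sigma2 = np.log1p(config.icv_cv**2)
    icv = rng.lognormal(np.log(config.icv_mean) - sigma2 / 2.0, np.sqrt(sigma2), n)

    is_max = is_scores.max()
    is_norm = is_scores / is_max if is_max > 0 else np.zeros(n)
    w = np.sqrt(config.coupling_base + config.coupling_slope * is_norm)
    factors = rng.standard_normal((n, len(components)))

    means = default_roi_means(config.scheme_mode)
    means.update(dict(config.roi_means))
    cvs = {r: config.roi_cv for r in scheme.names}
    cvs.update(dict(config.roi_cvs))
    mu = np.array([means[r] for r in scheme.names])
    cv = np.array([cvs[r] for r in scheme.names])
    if (mu <= 0).any() or (cv <= 0).any():
        raise ConfigError("ROI baseline volumes and CVs must be positive")
    tau = np.sqrt(np.log1p(cv**2))
    eps = rng.normal(0.0, 1.0, (n, len(scheme.names))) * tau[None, :]
    volumes = mu[None, :] * (icv[:, None] / config.icv_mean) * np.exp(eps)

    col = {r: i for i, r in enumerate(scheme.names)}
    sigma = mu * cv
    for c, comp in enumerate(components):
        for roi in comp:
            volumes[:, col[roi]] += sigma[col[roi]] * loadings[roi] * w * factors[:, c]
    for roi, slope in config.volume_effect_rois:
        volumes[:, col[roi]] += slope * is_scores

    floor = 0.01 * mu[None, :]
    clipped = volumes < floor
    clip_count = int(clipped.sum())
    if clip_count:
        warnings.warn(
            f"{clip_count} synthetic volume(s) clipped to the positivity floor",
            stacklevel=2,
        )
        volumes = np.where(clipped, np.broadcast_to(floor, volumes.shape), volumes)

    pheno = pd.DataFrame(
        {
            "age": age,
            "iq": iq,
            "icv": icv,
            **{name: scores[name] for name in SUBSCALES},
        },
        index=pd.Index(subject_ids, name="subject_id"),
    )
    vol = pd.DataFrame(
        volumes, index=pd.Index(subject_ids, name="subject_id"), columns=scheme.names
    )
    truth = SyntheticTruth(
        tuple(
            (x, y, loadings[x] * loadings[y])
            for x, y in (tuple(sorted(p)) for p in config.coupled_pairs)
        ),
        tuple(config.volume_effect_rois),
        w,
        pd.DataFrame(
            factors,
            index=pd.Index(subject_ids, name="subject_id"),
            columns=[f"component_{c + 1}" for c in range(len(components))],
        ),
        clip_count,
    )
    return CohortTable(pheno), VolumeTable(vol, scheme), truth


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

#: Named generator presets used by tests, the CLI and the fixture suite.
PRESETS: dict[str, GeneratorConfig] = {
    "planted-coupling": GeneratorConfig(),
    "null": GeneratorConfig(coupling_slope=0.0, volume_effect_rois=()),
    "planted-volume": GeneratorConfig(coupled_pairs=(), roi_loadings=(), coupling_slope=0.0),
    "tiny": GeneratorConfig(n_subjects=8, coupled_pairs=(), roi_loadings=(),
                            coupling_slope=0.0, volume_effect_rois=()),
}


def preset_config(name: str, seed: int, n_subjects: int | None = None) -> GeneratorConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = replace(PRESETS[name], seed=seed)
    if n_subjects is not None:
        cfg = replace(cfg, n_subjects=n_subjects)
    return cfg


def write_truth(truth: SyntheticTruth, effects_path: Path, latents_path: Path) -> None:
    rows = [
        {"kind": "coupled_pair", "roi_x": x, "roi_y": y, "effect": a}
        for x, y, a in truth.coupled_pairs
    ] + [
        {"kind": "volume_effect", "roi_x": roi, "roi_y": "", "effect": slope}
        for roi, slope in truth.volume_effect_rois
    ]
    pd.DataFrame(rows, columns=["kind", "roi_x", "roi_y", "effect"]).to_csv(
        effects_path, sep="\t", index=False
    )
    lat = truth.latent_factors.copy()
    lat.insert(0, "w", truth.latent_w)
    lat.to_csv(latents_path, sep="\t", index_label="subject_id")


def make_fixture_suite(out_dir: str | Path, base_seed: int = 1000) -> dict[str, dict[str, Path]]:
    """Write the canonical fixture cohorts (null, planted-coupling,
    planted-volume-effect, tiny) with truth files and a seed manifest.

    Deterministic: rerunning with the same ``base_seed`` rewrites byte-
    identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    manifest_lines = []
    for offset, name in enumerate(["null", "planted-coupling", "planted-volume", "tiny"]):
        seed = base_seed + offset
        cfg = preset_config(name, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, volumes, truth = generate_cohort(cfg)
        stem = name.replace("-", "_")
        paths = {
            "phenotypes": out / f"{stem}_phenotypes.tsv",
            "volumes": out / f"{stem}_volumes.tsv",
            "truth": out / f"{stem}_truth.tsv",
            "latents": out / f"{stem}_latents.tsv",
        }
        write_phenotypes(cohort, paths["phenotypes"])
        write_volume_table(volumes, paths["volumes"])
        write_truth(truth, paths["truth"], paths["latents"])
        manifest_lines.append(f"{name} seed={seed} n={cfg.n_subjects}")
        written[name] = paths
    (out / "manifest.txt").write_text("\n".join(manifest_lines) + "\n")
    return written
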