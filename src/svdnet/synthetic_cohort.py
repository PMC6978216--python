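"""Synthetic two-wave SVD cohort generator with known injected effects.

Generates a complete test bed for the pipeline — per-subject weighted
connectomes at two imaging waves, demographics, small-vessel-disease
markers, cognitive scores and incident dementia — with every effect size
recorded in a ground-truth ledger so that parameter recovery can be
checked at each analysis stage.

The default calibration reproduces the printed population parameters of
the cohort the pipeline is designed for: ~270 subjects aged 67.9 +/- 7.8
years, two waves 3.4 +/- 0.2 years apart, log-normal WMH volumes with
median 2.8 ml (IQR 1.3-7.8), a 90-region parcellation whose 8 designated
rich-club nodes carry the highest degrees, rich-club connection strength
declining by 0.44 on average between waves (feeder -0.03, peripheral
-0.02, spreads matched to the printed confidence intervals), cognition
driven by network decline with zero direct WMH effect (complete
mediation by construction), and a ~7% dementia rate governed by baseline
global efficiency and peripheral strength.

Generative model, in causal order:

1. a latent SVD burden z_i ~ N(0,1) per subject drives WMH volume
   (log-normal, exactly monotone in z_i), lacune/microbleed counts
   (Poisson with log-rate linear in z_i) and network degradation;
2. baseline connectomes perturb a cohort-level template graph drawn
   from class-wise edge probabilities (rich-rich high, feeder middle,
   peripheral solved to hit the density target); all weights are scaled
   down by exp(-wmh_network_effect * z_i) and by a subject-level
   log-normal factor (individual differences independent of burden);
3. follow-up connectomes shrink each connection class multiplicatively
   so the subject's class-mean strength changes by
   d_ic ~ N(decline_mean_c, decline_sd_c), and lose a small random
   fraction of edges (so density and efficiency decline too);
4. cognition composites load on the injected peripheral-strength
   decline (plus an optional direct WMH effect, default 0);
5. dementia ~ Bernoulli(expit(c + s_eff * z(efficiency) +
   s_per * z(peripheral strength))), both measures at baseline, with c
   solved so the cohort-average risk equals the configured base rate.

All randomness flows from one seed through named substreams so modules
can be regression-tested independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .connectome import (
    DEFAULT_PARCELLATION,
    ConnectivityMatrix,
    Parcellation,
    StreamlineRecord,
    StreamlineSet,
)
from .network_metrics import EDGE_CLASSES, global_efficiency

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "streamlines_for_matrix",
    "wmh_lognormal_params",
]

# Plausible baseline norms (mean, SD) per derived test score, used only
# in raw-score mode to map synthetic z-scores onto test-native scales.
_TEST_NORMS = {
    "ravlt_immediate": (42.0, 10.0),
    "ravlt_delayed": (8.5, 3.0),
    "rcft_immediate": (18.0, 6.0),
    "rcft_delayed": (17.0, 6.0),
    "ppmst1_sat": (1.2, 0.3),
    "ppmst2_sat": (0.9, 0.25),
    "ppmst3_sat": (0.7, 0.2),
    "stroop_read_sat": (2.2, 0.4),
    "stroop_name_sat": (1.8, 0.35),
    "stroop_interference": (0.55, 0.12),
    "sdst": (45.0, 10.0),
    "fluency": (22.0, 6.0),
    "vsat_sat": (0.9, 0.25),
}
# Item counts used to turn a SAT score into (n_correct, time) pairs.
_SAT_ITEMS = {
    "ppmst1_sat": ("ppmst1", 40),
    "ppmst2_sat": ("ppmst2", 40),
    "ppmst3_sat": ("ppmst3", 40),
    "stroop_read_sat": ("stroop_read", 100),
    "stroop_name_sat": ("stroop_name", 100),
    "vsat_sat": ("vsat", 50),
}

COMPOSITES = ("cognitive_index", "memory", "psychomotor_speed", "executive_function")


def wmh_lognormal_params(median_ml: float, iqr_ml: tuple[float, float]) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a printed median and IQR width.

    mu is the log median; sigma is fitted to the interquartile ratio
    q75/q25 (the printed IQR is not exactly symmetric about the median on
    the log scale, so a two-parameter log-normal matches the median and
    the IQR *width*, not each quartile individually).
    """
    q25, q75 = iqr_ml
    if not (0 < q25 < q75) or median_ml <= 0:
        raise ValueError("need 0 < q25 < q75 and a positive median")
    z75 = 0.6744897501960817  # standard normal 75th percentile
    return float(np.log(median_ml)), float(np.log(q75 / q25) / (2 * z75))


@dataclass
class GeneratorConfig:
    """All dials of the synthetic cohort; defaults are the shipped
    calibration (see module docstring)."""

    n_subjects: int = 270
    seed: int = 0
    parcellation: Parcellation = field(default_factory=lambda: DEFAULT_PARCELLATION)

    # demographics
    age_mean: float = 67.9
    age_sd: float = 7.8
    prop_male: float = 0.596
    education_mean: float = 10.1
    education_sd: float = 1.5
    hypertension_prevalence: float = 0.596
    follow_up_years_mean: float = 3.4
    follow_up_years_sd: float = 0.2

    # SVD markers
    wmh_median_ml: float = 2.8
    wmh_iqr_ml: tuple[float, float] = (1.3, 7.8)
    wmh_progression_log_mean: float = 0.25  # log-ratio follow-up/baseline
    wmh_progression_log_sd: float = 0.15
    lacune_base_rate: float = 0.30          # Poisson mean at z = 0
    microbleed_base_rate: float = 0.20
    svd_count_loading: float = 0.8          # log-rate increase per SD burden
    incident_lacune_rate: float = 0.08
    incident_microbleed_rate: float = 0.06

    # brain volumes (ml); total = grey + white
    grey_matter_ml_mean: float = 610.6
    grey_matter_ml_sd: float = 50.1
    white_matter_ml_mean: float = 455.7
    white_matter_ml_sd: float = 44.0
    brain_volume_burden_effect: float = 20.0  # ml lost per SD burden

    # baseline network model
    density_target: float = 0.15
    p_rich_rich: float = 0.9
    p_feeder: float = 0.35
    class_weight_means: tuple[float, float, float] = (12.0, 5.0, 3.0)
    weight_log_sd: float = 0.3
    edge_rewire_prob: float = 0.03
    subject_edge_jitter_sd: float = 0.15
    subject_scale_log_sd: float = 0.10
    wmh_network_effect: float = 0.15  # log-weight reduction per SD burden

    # decline model: change in class-mean strength between waves, plus a
    # small random edge loss so density and efficiency also decline
    decline_mean: tuple[float, float, float] = (-0.44, -0.03, -0.02)
    decline_sd: tuple[float, float, float] = (1.55, 0.40, 0.18)
    followup_edge_dropout: float = 0.01

    # cognition: loadings of standardized injected peripheral decline on
    # each composite's change score, plus optional direct WMH effect
    cognition_network_effect: dict[str, float] = field(
        default_factory=lambda: {
            "cognitive_index": 0.15,
            "memory": 0.0,
            "psychomotor_speed": 0.15,
            "executive_function": 0.12,
        }
    )
    direct_wmh_cognition_effect: float = 0.0
    baseline_cognition_network_loading: float = 0.3
    cognition_noise_sd: float = 0.95
    raw_scores: bool = False

    # dementia model (log-odds per SD of the baseline measure)
    dementia_base_rate: float = 23 / 329
    dementia_efficiency_slope: float = -1.75
    dementia_peripheral_slope: float = -0.9

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for name in ("age_sd", "education_sd", "follow_up_years_sd",
                     "wmh_progression_log_sd", "weight_log_sd",
                     "subject_edge_jitter_sd", "subject_scale_log_sd",
                     "cognition_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("prop_male", "hypertension_prevalence", "dementia_base_rate",
                     "p_rich_rich", "p_feeder", "edge_rewire_prob",
                     "followup_edge_dropout"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.density_target <= 1:
            raise ValueError("density_target must be in (0, 1]")
        if any(sd < 0 for sd in self.decline_sd):
            raise ValueError("decline SDs must be nonnegative")


@dataclass
class SyntheticCohort:
    """Generated cohort: long-format table, matrices, and ground truth."""

    cohort: pd.DataFrame                      # one row per subject-wave
    matrices: dict[tuple[str, str], ConnectivityMatrix]
    ground_truth: dict
    config: GeneratorConfig

    @property
    def subject_ids(self) -> list[str]:
        return list(self.cohort["subject_id"].unique())

    def baseline(self) -> pd.DataFrame:
        return self.cohort[self.cohort["wave"] == "baseline"].reset_index(drop=True)

    def followup(self) -> pd.DataFrame:
        return self.cohort[self.cohort["wave"] == "followup"].reset_index(drop=True)


def _edge_class_index(parc: Parcellation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pair indices and their class (0 rich, 1 feeder, 2 peripheral)."""
    n = parc.n_regions
    iu, ju = np.triu_indices(n, k=1)
    rich = parc.rich_club_mask
    n_rich = rich[iu].astype(int) + rich[ju].astype(int)
    return iu, ju, 2 - n_rich


def _template_edges(cfg: GeneratorConfig, rng: np.random.Generator):
    """Draw the cohort-level template edge set from class probabilities."""
    parc = cfg.parcellation
    iu, ju, cls = _edge_class_index(parc)
    n_pairs = iu.size
    counts = np.bincount(cls, minlength=3)
    target_edges = cfg.density_target * n_pairs
    reserved = cfg.p_rich_rich * counts[0] + cfg.p_feeder * counts[1]
    if counts[2] == 0:
        p_per = 0.0
        if abs(reserved - target_edges) > 0.5:
            raise ValueError("density target unreachable with no peripheral pairs")
    else:
        p_per = (target_edges - reserved) / counts[2]
    if not 0 < p_per < 1:
        raise ValueError(
            "unsatisfiable density/rich-club configuration: implied peripheral "
            f"edge probability {p_per:.3f} outside (0, 1)"
        )
    p_edge = np.array([cfg.p_rich_rich, cfg.p_feeder, p_per])[cls]
    present = rng.random(n_pairs) < p_edge
    mu = np.log(np.asarray(cfg.class_weight_means))[cls] - cfg.weight_log_sd**2 / 2
    weights = np.exp(rng.normal(mu, cfg.weight_log_sd))
    return iu, ju, cls, present, weights, p_edge


def _safe_z(v: np.ndarray) -> np.ndarray:
    """Standardize; all-zero when degenerate (n < 2 or zero spread)."""
    sd = np.nanstd(v, ddof=1) if v.size > 1 else 0.0
    if not np.isfinite(sd) or sd == 0:
        return np.zeros_like(v)
    return (v - np.nanmean(v)) / sd


def _class_means(weights_vec: np.ndarray, cls: np.ndarray) -> np.ndarray:
    """Mean weight of present edges per class (NaN when class empty)."""
    out = np.full(3, np.nan)
    for c in range(3):
        sel = (cls == c) & (weights_vec > 0)
        if sel.any():
            out[c] = weights_vec[sel].mean()
    return out


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full two-wave cohort; reproducible given config + seed."""
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    root = np.random.SeedSequence(seed)
    streams = dict(zip(
        ("demographics", "template", "networks", "cognition", "dementia"),
        (np.random.default_rng(s) for s in root.spawn(5)),
    ))
    parc = cfg.parcellation
    n = cfg.n_subjects
    subject_ids = [f"sub-{i+1:04d}" for i in range(n)]

    # --- demographics and SVD markers --------------------------------
    rng = streams["demographics"]
    burden = rng.standard_normal(n)  # latent SVD burden
    age = cfg.age_mean + cfg.age_sd * rng.standard_normal(n)
    male = (rng.random(n) < cfg.prop_male).astype(int)
    education = np.clip(
        cfg.education_mean + cfg.education_sd * rng.standard_normal(n), 0, None
    )
    # hypertension more likely with burden (questionnaire attribute only)
    hyper = (rng.random(n) < expit(logit(cfg.hypertension_prevalence) + 0.5 * burden)).astype(int)
    years = np.clip(
        cfg.follow_up_years_mean + cfg.follow_up_years_sd * rng.standard_normal(n), 0.5, None
    )
    mu_w, sigma_w = wmh_lognormal_params(cfg.wmh_median_ml, cfg.wmh_iqr_ml)
    wmh_b = np.exp(mu_w + sigma_w * burden)
    wmh_f = wmh_b * np.exp(
        cfg.wmh_progression_log_mean + cfg.wmh_progression_log_sd * rng.standard_normal(n)
    )
    lacunes = rng.poisson(cfg.lacune_base_rate * np.exp(cfg.svd_count_loading * burden) / 2)
    microbleeds = rng.poisson(cfg.microbleed_base_rate * np.exp(cfg.svd_count_loading * burden) / 2)
    inc_lacunes = rng.poisson(cfg.incident_lacune_rate * np.exp(cfg.svd_count_loading * burden) / 2)
    inc_microbleeds = rng.poisson(cfg.incident_microbleed_rate * np.exp(cfg.svd_count_loading * burden) / 2)
    gm = cfg.grey_matter_ml_mean + cfg.grey_matter_ml_sd * rng.standard_normal(n) \
        - 0.6 * cfg.brain_volume_burden_effect * burden
    wm = cfg.white_matter_ml_mean + cfg.white_matter_ml_sd * rng.standard_normal(n) \
        - 0.4 * cfg.brain_volume_burden_effect * burden
    tbv = gm + wm
    atrophy = np.abs(rng.normal(8.0, 4.0, n))  # ml lost over follow-up

    # --- baseline and follow-up connectomes --------------------------
    iu, ju, cls, t_present, t_weights, p_edge = _template_edges(cfg, streams["template"])
    rng = streams["networks"]
    n_regions = parc.n_regions
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    injected_decline = np.zeros((n, 3))
    base_class_means = np.zeros((n, 3))
    eff_b = np.zeros(n)
    subj_scale = np.exp(rng.normal(0.0, cfg.subject_scale_log_sd, n))

    # rewire: drop present template edges / add absent pairs with
    # class-preserving expected counts
    p_add = np.clip(cfg.edge_rewire_prob * p_edge / np.maximum(1 - p_edge, 1e-12), 0, 1)
    decl_mean = np.asarray(cfg.decline_mean)
    decl_sd = np.asarray(cfg.decline_sd)
    mu_cls = np.log(np.asarray(cfg.class_weight_means))[cls] - cfg.weight_log_sd**2 / 2

    for s in range(n):
        u = rng.random(iu.size)
        present = np.where(t_present, u >= cfg.edge_rewire_prob, u < p_add)
        w_vec = np.where(
            t_present & present,
            t_weights * np.exp(rng.normal(0.0, cfg.subject_edge_jitter_sd, iu.size)),
            np.exp(rng.normal(mu_cls, cfg.weight_log_sd)),
        )
        w_vec = np.where(present, w_vec, 0.0)
        w_vec *= subj_scale[s] * np.exp(-cfg.wmh_network_effect * burden[s])

        W = np.zeros((n_regions, n_regions))
        W[iu, ju] = w_vec
        W += W.T
        mb = ConnectivityMatrix(W, parc)
        matrices[(subject_ids[s], "baseline")] = mb
        base_class_means[s] = _class_means(w_vec, cls)
        eff_b[s] = global_efficiency(mb)

        d = rng.normal(decl_mean, decl_sd)
        factors = np.ones(3)
        for c in range(3):
            m = base_class_means[s, c]
            if np.isfinite(m) and m > 0:
                factors[c] = max((m + d[c]) / m, 0.05)
        injected_decline[s] = np.where(
            np.isfinite(base_class_means[s]),
            (factors - 1.0) * base_class_means[s],
            0.0,
        )
        w_f = w_vec * factors[cls]
        if cfg.followup_edge_dropout > 0:
            w_f = np.where(rng.random(iu.size) < cfg.followup_edge_dropout, 0.0, w_f)
        Wf = np.zeros((n_regions, n_regions))
        Wf[iu, ju] = w_f
        Wf += Wf.T
        matrices[(subject_ids[s], "followup")] = ConnectivityMatrix(Wf, parc)

    per_b = base_class_means[:, 2]  # baseline peripheral class-mean strength

    # --- cognition ----------------------------------------------------
    rng = streams["cognition"]
    log_wmh_z = (np.log(wmh_b) - mu_w) / sigma_w  # == burden by construction
    d_per_z = _safe_z(injected_decline[:, 2])
    health = -cfg.wmh_network_effect * burden + np.log(subj_scale)
    health_z = _safe_z(health)
    comp_b: dict[str, np.ndarray] = {}
    comp_f: dict[str, np.ndarray] = {}
    for comp in COMPOSITES:
        b_net = cfg.cognition_network_effect.get(comp, 0.0)
        base = cfg.baseline_cognition_network_loading * health_z \
            + cfg.cognition_noise_sd * rng.standard_normal(n)
        delta = b_net * d_per_z \
            + cfg.direct_wmh_cognition_effect * log_wmh_z \
            + 0.3 * rng.standard_normal(n)
        comp_b[comp] = base
        comp_f[comp] = base + delta

    # --- dementia -----------------------------------------------------
    rng = streams["dementia"]
    eff_z = _safe_z(eff_b)
    per_z = _safe_z(per_b)
    eta = cfg.dementia_efficiency_slope * eff_z + cfg.dementia_peripheral_slope * np.nan_to_num(per_z)
    if cfg.dementia_base_rate in (0.0, 1.0):
        intercept = np.inf if cfg.dementia_base_rate == 1.0 else -np.inf
        prob = np.full(n, cfg.dementia_base_rate)
    else:
        intercept = brentq(
            lambda c: expit(c + eta).mean() - cfg.dementia_base_rate, -50, 50
        )
        prob = expit(intercept + eta)
    dementia = (rng.random(n) < prob).astype(int)

    # --- assemble long-format cohort table ---------------------------
    rows = []
    for wave in ("baseline", "followup"):
        df = pd.DataFrame({
            "subject_id": subject_ids,
            "wave": wave,
            "age": age if wave == "baseline" else age + years,
            "male": male,
            "education_years": education,
            "hypertension": hyper,
            "follow_up_years": years,
            "wmh_ml": wmh_b if wave == "baseline" else wmh_f,
            "lacune_count": lacunes if wave == "baseline" else lacunes + inc_lacunes,
            "microbleed_count": microbleeds if wave == "baseline" else microbleeds + inc_microbleeds,
            "total_brain_ml": tbv if wave == "baseline" else tbv - atrophy,
            "grey_matter_ml": gm,
            "white_matter_ml": wm,
            "dementia_followup": dementia,
        })
        for comp in COMPOSITES:
            df[comp] = comp_b[comp] if wave == "baseline" else comp_f[comp]
        rows.append(df)
    cohort = pd.concat(rows, ignore_index=True)

    ground_truth = {
        "seed": int(seed),
        "config": _config_to_jsonable(cfg),
        "wmh_lognormal": {"mu": mu_w, "sigma": sigma_w},
        "decline_mean": list(cfg.decline_mean),
        "decline_sd": list(cfg.decline_sd),
        "injected_decline_mean_by_class": {
            c: float(injected_decline[:, k].mean()) for k, c in enumerate(EDGE_CLASSES)
        },
        "direct_wmh_cognition_effect": cfg.direct_wmh_cognition_effect,
        "cognition_network_effect": dict(cfg.cognition_network_effect),
        "dementia_intercept": float(intercept),
        "dementia_rate_realized": float(dementia.mean()),
        "latent_burden": burden.tolist(),
        "injected_decline": injected_decline.tolist(),
    }
    cohort_obj = SyntheticCohort(cohort, matrices, ground_truth, cfg)
    if cfg.raw_scores:
        _attach_raw_scores(cohort_obj, streams["cognition"])
    return cohort_obj


def _attach_raw_scores(cohort: SyntheticCohort, rng: np.random.Generator) -> None:
    """Synthesize per-test raw scores consistent with the composites.

    Each test's z-score is its domain composite plus test-specific noise;
    raw scores are mapped through fixed plausible norms.  SAT tests are
    emitted as (n_correct, time) with time = n_correct / SAT so the
    derived score is exact; the Stroop color-word SAT is back-solved from
    the interference target.  The stored composite columns are then
    *recomputed* through the cognition module so the table is exactly
    self-consistent.
    """
    from . import cognition as cog

    df = cohort.cohort
    test_noise = 0.5
    domain_of = {}
    for domain, members in cog.DOMAINS.items():
        if domain == "cognitive_index":
            continue
        for t in members:
            domain_of[t] = domain

    n_rows = len(df)
    zcols = {}
    for t in cog.DERIVED_TESTS:
        target = df[domain_of[t]].to_numpy()
        zcols[t] = target + test_noise * rng.standard_normal(n_rows)

    raw = {}
    for t, (m, sd) in _TEST_NORMS.items():
        raw[t] = np.clip(m + sd * zcols[t], 1e-3, None)
    for sat_name, (prefix, items) in _SAT_ITEMS.items():
        n_correct = np.round(
            np.clip(items * (0.85 + 0.05 * rng.standard_normal(n_rows)), 1, items)
        )
        raw[f"{prefix}_n_correct"] = n_correct
        raw[f"{prefix}_time_s"] = n_correct / raw[sat_name]
    # Stroop color-word from the interference target and the read/name SATs
    cw_sat = raw["stroop_interference"] * (raw["stroop_read_sat"] + raw["stroop_name_sat"]) / 2
    cw_n = np.round(np.clip(100 * (0.8 + 0.05 * rng.standard_normal(n_rows)), 1, 100))
    raw["stroop_cw_n_correct"] = cw_n
    raw["stroop_cw_time_s"] = cw_n / np.clip(cw_sat, 1e-6, None)

    keep = ["ravlt_immediate", "ravlt_delayed", "rcft_immediate", "rcft_delayed",
            "sdst", "fluency"]
    for t in keep:
        df[t] = raw[t]
    for prefix in ("ppmst1", "ppmst2", "ppmst3", "stroop_read", "stroop_name",
                   "stroop_cw", "vsat"):
        df[f"{prefix}_n_correct"] = raw[f"{prefix}_n_correct"]
        df[f"{prefix}_time_s"] = raw[f"{prefix}_time_s"]

    # recompute composites through the cognition module (exact consistency)
    records = [
        cog.CognitiveRecord(
            subject_id=row.subject_id, wave=row.wave,
            **{f: getattr(row, f) for f in (
                "ravlt_immediate", "ravlt_delayed", "rcft_immediate", "rcft_delayed",
                "sdst", "fluency",
            )},
            **{f"{p}_{suf}": getattr(row, f"{p}_{suf}")
               for p in ("ppmst1", "ppmst2", "ppmst3", "stroop_read", "stroop_name",
                         "stroop_cw", "vsat")
               for suf in ("n_correct", "time_s")},
        )
        for row in df.itertuples(index=False)
    ]
    stats = cog.baseline_stats_from_cohort(records)
    for i, rec in enumerate(records):
        comp = cog.compose_domains(rec, stats)
        for c in COMPOSITES:
            df.iloc[i, df.columns.get_loc(c)] = getattr(comp, c)


def streamlines_for_matrix(
    target: ConnectivityMatrix,
    seed: int = 0,
    k: int = 3,
    scale: float = 1.0,
    subject_id: str = "",
    wave: str = "baseline",
) -> StreamlineSet:
    """Invert a connectivity matrix into streamline records.

    Emits k records of equal length per present edge, with length
    l = k * scale / weight so that scale * sum(1/l) reproduces the target
    weight exactly.  The seed only shuffles record order.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    w = target.weights
    if np.any(w < 0):
        raise ValueError("target weights must be nonnegative")
    labels = target.parcellation.labels
    iu, ju = np.nonzero(np.triu(w, k=1))
    records = []
    for i, j in zip(iu.tolist(), ju.tolist()):
        length = k * scale / w[i, j]
        records.extend(
            StreamlineRecord(labels[i], labels[j], length) for _ in range(k)
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    records = [records[q] for q in order]
    return StreamlineSet(records, scale=scale, subject_id=subject_id, wave=wave)


def _config_to_jsonable(cfg: GeneratorConfig) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, Parcellation):
            out[f.name] = {
                "labels": list(v.labels),
                "rich_club_labels": list(v.rich_club_labels),
            }
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


def config_from_jsonable(data: dict) -> GeneratorConfig:
    """Rebuild a GeneratorConfig from its JSON form."""
    kwargs = dict(data)
    if "parcellation" in kwargs and isinstance(kwargs["parcellation"], dict):
        p = kwargs["parcellation"]
        kwargs["parcellation"] = Parcellation(
            tuple(p["labels"]), tuple(p.get("rich_club_labels", ()))
        )
    for name in ("wmh_iqr_ml", "class_weight_means", "decline_mean", "decline_sd"):
        if name in kwargs and isinstance(kwargs[name], list):
            kwargs[name] = tuple(kwargs[name])
    return GeneratorConfig(**kwargs)
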