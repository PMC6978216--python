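"""Composite cognition scores from a neuropsychological battery.

Raw test scores are first reduced to one derived score per test
(speed-accuracy trade-off for timed tests, Stroop interference ratio),
z-scored against the *baseline* study population (follow-up scores use
the same baseline mean/SD, so longitudinal change is preserved on the z
scale), and averaged into domain composites:

* memory — RAVLT immediate/delayed recall, RCFT immediate/delayed
  recall, SAT of the 2- and 3-letter memory-scanning subtasks;
* psychomotor speed — SAT of the 1-letter memory-scanning subtask,
  Stroop reading and color-naming SATs, symbol-digit substitution;
* executive function — Stroop interference, verbal fluency, verbal
  series attention SAT;
* cognitive index — mean z over the whole battery.

A composite is the mean of its *available* constituent z-scores and is
missing only when all constituents are missing.  Change scores are
follow-up minus baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "CognitiveRecord",
    "CompositeScores",
    "BaselineStats",
    "sat_score",
    "stroop_interference",
    "zscore_vs_baseline",
    "derive_test_scores",
    "baseline_stats_from_cohort",
    "compose_domains",
    "delta_scores",
    "DERIVED_TESTS",
    "DOMAINS",
]

_MISSING = float("nan")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class CognitiveRecord:
    """Raw scores of one subject at one wave; any score may be missing."""

    subject_id: str
    wave: str
    ravlt_immediate: float = _MISSING
    ravlt_delayed: float = _MISSING
    rcft_immediate: float = _MISSING
    rcft_delayed: float = _MISSING
    ppmst1_n_correct: float = _MISSING
    ppmst1_time_s: float = _MISSING
    ppmst2_n_correct: float = _MISSING
    ppmst2_time_s: float = _MISSING
    ppmst3_n_correct: float = _MISSING
    ppmst3_time_s: float = _MISSING
    stroop_read_n_correct: float = _MISSING
    stroop_read_time_s: float = _MISSING
    stroop_name_n_correct: float = _MISSING
    stroop_name_time_s: float = _MISSING
    stroop_cw_n_correct: float = _MISSING
    stroop_cw_time_s: float = _MISSING
    sdst: float = _MISSING
    fluency: float = _MISSING
    vsat_n_correct: float = _MISSING
    vsat_time_s: float = _MISSING

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_time_s") and not _is_missing(v) and not v > 0:
                raise ValueError(f"{f.name} must be positive when present, got {v}")
            if f.name.endswith("_n_correct") and not _is_missing(v) and v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")


# Derived per-test scores in battery order.
DERIVED_TESTS = (
    "ravlt_immediate", "ravlt_delayed", "rcft_immediate", "rcft_delayed",
    "ppmst1_sat", "ppmst2_sat", "ppmst3_sat",
    "stroop_read_sat", "stroop_name_sat", "stroop_interference",
    "sdst", "fluency", "vsat_sat",
)

DOMAINS = {
    "memory": (
        "ravlt_immediate", "ravlt_delayed", "rcft_immediate",
        "rcft_delayed", "ppmst2_sat", "ppmst3_sat",
    ),
    "psychomotor_speed": (
        "ppmst1_sat", "stroop_read_sat", "stroop_name_sat", "sdst",
    ),
    "executive_function": ("stroop_interference", "fluency", "vsat_sat"),
    "cognitive_index": DERIVED_TESTS,
}


@dataclass
class CompositeScores:
    subject_id: str
    wave: str
    test_z: dict[str, float] = field(default_factory=dict)
    cognitive_index: float = _MISSING
    memory: float = _MISSING
    psychomotor_speed: float = _MISSING
    executive_function: float = _MISSING


def sat_score(n_correct: float, time_s: float) -> float:
    """Speed-accuracy trade-off: correct responses per second.

    Higher is better.  Returns NaN if either input is missing.
    """
    if _is_missing(n_correct) or _is_missing(time_s):
        return _MISSING
    if time_s <= 0:
        raise ValueError(f"completion time must be positive, got {time_s}")
    if n_correct < 0:
        raise ValueError(f"n_correct must be nonnegative, got {n_correct}")
    return n_correct / time_s


def stroop_interference(sat_cw: float, sat_read: float, sat_name: float) -> float:
    """Color-word SAT divided by the mean of reading and naming SATs.

    Under the SAT convention this ratio *decreases* with more
    interference.  Returns NaN (with a warning) on a zero denominator or
    any missing input.
    """
    if any(_is_missing(v) for v in (sat_cw, sat_read, sat_name)):
        return _MISSING
    denom = (sat_read + sat_name) / 2.0
    if denom <= 0:
        warnings.warn("Stroop interference undefined: zero denominator", stacklevel=2)
        return _MISSING
    return sat_cw / denom


def zscore_vs_baseline(raw: float, baseline_mean: float, baseline_sd: float) -> float:
    """Standardize against the baseline population mean and SD."""
    if baseline_sd <= 0:
        raise ValueError(f"baseline SD must be positive, got {baseline_sd}")
    if _is_missing(raw):
        return _MISSING
    return (raw - baseline_mean) / baseline_sd


def derive_test_scores(record: CognitiveRecord) -> dict[str, float]:
    """Reduce raw scores to one derived score per battery test."""
    r = record
    out = {
        "ravlt_immediate": r.ravlt_immediate,
        "ravlt_delayed": r.ravlt_delayed,
        "rcft_immediate": r.rcft_immediate,
        "rcft_delayed": r.rcft_delayed,
        "ppmst1_sat": sat_score(r.ppmst1_n_correct, r.ppmst1_time_s),
        "ppmst2_sat": sat_score(r.ppmst2_n_correct, r.ppmst2_time_s),
        "ppmst3_sat": sat_score(r.ppmst3_n_correct, r.ppmst3_time_s),
        "stroop_read_sat": sat_score(r.stroop_read_n_correct, r.stroop_read_time_s),
        "stroop_name_sat": sat_score(r.stroop_name_n_correct, r.stroop_name_time_s),
        "sdst": r.sdst,
        "fluency": r.fluency,
        "vsat_sat": sat_score(r.vsat_n_correct, r.vsat_time_s),
    }
    out["stroop_interference"] = stroop_interference(
        sat_score(r.stroop_cw_n_correct, r.stroop_cw_time_s),
        out["stroop_read_sat"],
        out["stroop_name_sat"],
    )
    return out


@dataclass(frozen=True)
class BaselineStats:
    """Per-test mean and SD of the baseline population."""

    mean: dict[str, float]
    sd: dict[str, float]

    def z(self, test: str, raw: float) -> float:
        return zscore_vs_baseline(raw, self.mean[test], self.sd[test])


def baseline_stats_from_cohort(records: list[CognitiveRecord]) -> BaselineStats:
    """Compute baseline-population mean/SD of every derived test score.

    Only records with ``wave == 'baseline'`` contribute; the sample SD
    (ddof=1) is used, as is standard for population norms.
    """
    rows = [derive_test_scores(r) for r in records if r.wave == "baseline"]
    if not rows:
        raise ValueError("no baseline records supplied")
    df = pd.DataFrame(rows)
    mean = df.mean().to_dict()
    sd = df.std(ddof=1).to_dict()
    return BaselineStats(mean=mean, sd=sd)


def compose_domains(record: CognitiveRecord, baseline_stats: BaselineStats) -> CompositeScores:
    """Z-score each derived test and average into the four composites."""
    derived = derive_test_scores(record)
    z = {t: baseline_stats.z(t, derived[t]) for t in DERIVED_TESTS}
    out = CompositeScores(record.subject_id, record.wave, test_z=z)
    for domain, members in DOMAINS.items():
        vals = [z[t] for t in members if not _is_missing(z[t])]
        setattr(out, domain, float(np.mean(vals)) if vals else _MISSING)
    return out


def delta_scores(followup: CompositeScores, baseline: CompositeScores) -> CompositeScores:
    """Follow-up minus baseline, per test z and per composite."""
    if followup.subject_id != baseline.subject_id:
        raise ValueError(
            f"subject mismatch: {followup.subject_id!r} vs {baseline.subject_id!r}"
        )

    def _sub(a: float, b: float) -> float:
        return _MISSING if _is_missing(a) or _is_missing(b) else a - b

    dz = {
        t: _sub(followup.test_z.get(t, _MISSING), baseline.test_z.get(t, _MISSING))
        for t in DERIVED_TESTS
    }
    out = CompositeScores(followup.subject_id, "delta", test_z=dz)
    for domain in DOMAINS:
        setattr(out, domain, _sub(getattr(followup, domain), getattr(baseline, domain)))
    return out
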