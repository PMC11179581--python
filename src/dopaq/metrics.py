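"""Headline neurodegeneration and redox statistics.

Two bespoke per-population statistics drive the analysis:

* **Oxidation ratio** — for a ratiometric redox sensor (roGFP2-ORP1), the
  background-corrected 405/488 excitation ratio of the injured population
  minus the same quantity for time-matched uninjured controls. Background is
  estimated from the transgene-negative (mCherry-negative) events of the same
  run, exploiting the mosaicism of extrachromosomal arrays::

      ratio_i = (405_i - mean405_mCh-) / (mean488_mCh+ - mean488_mCh-)
      oxidation_ratio = mean_i[injured ratio_i] - mean_i[uninjured ratio_i]

* **Dopaminergic GFP index** — per-worm GFP retention is the injured worm's
  head GFP peak divided by the mean uninjured head GFP peak of the same
  genotype/RNAi arm; with control and test retention means cΔ and tΔ::

      index = (cΔ - tΔ) / (cΔ - 1)

  Values > 0 are protective relative to the control arm, < 0 degenerative.

Both are exposed as plain functions and, for fitting with uncertainties and a
summary table, as Model/Results pairs (:class:`OxidationModel`,
:class:`GfpIndexModel`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .flow import Condition, GatedCondition, WormPopulation

__all__ = [
    "background_corrected_ratio",
    "oxidation_ratio",
    "gfp_retention",
    "dopaminergic_gfp_index",
    "double_normalize",
    "aging_timecourse_normalize",
    "OxidationResult",
    "RetentionSummary",
    "GfpIndexResult",
    "OxidationModel",
    "GfpIndexModel",
]


# ---------------------------------------------------------------------------
# core formulas


def background_corrected_ratio(
    gated: GatedCondition, per_event: bool = True
) -> tuple[np.ndarray, float]:
    """Background-corrected 405/488 ratio of a gated condition.

    For each carrier (mCh+) event the 405 signal has the mCh- mean subtracted;
    the denominator is the condition-level difference of 488 means. Returns
    ``(per_event_ratios, condition_mean)``.

    With ``per_event=False`` the numerator also uses the condition mean
    (ratio-of-means reading of the formula); both readings give the same
    condition mean, but only the per-event form yields per-worm values for
    outlier removal and confidence intervals.
    """
    if gated.n_pos < 1:
        raise ValueError("no mCh+ events")
    if gated.n_neg < 1:
        raise ValueError("no background events (empty mCh- population)")
    pos405 = gated.mch_pos["gfp405_peak"].to_numpy(dtype=float)
    pos488 = gated.mch_pos["gfp488_peak"].to_numpy(dtype=float)
    neg405 = float(gated.mch_neg["gfp405_peak"].mean())
    neg488 = float(gated.mch_neg["gfp488_peak"].mean())
    denom = float(pos488.mean()) - neg488
    if denom <= 0:
        raise ValueError("signal not above background: mean488(mCh+) <= mean488(mCh-)")
    if per_event:
        ratios = (pos405 - neg405) / denom
    else:
        ratios = np.array([(pos405.mean() - neg405) / denom])
    return ratios, float(ratios.mean())


@dataclass
class OxidationResult:
    """Oxidation ratio of an injured condition against its uninjured control."""

    oxidation_ratio: float
    injured_mean: float
    uninjured_mean: float
    per_event_ratios: np.ndarray
    uninjured_per_event_ratios: np.ndarray
    n_pos_injured: int
    n_neg_injured: int
    n_pos_uninjured: int
    n_neg_uninjured: int
    timepoint_h: float = 0.0
    ci95: tuple[float, float] | None = None

    def summary(self) -> pd.DataFrame:
        rows = {
            "oxidation_ratio": self.oxidation_ratio,
            "injured_mean_405_488": self.injured_mean,
            "uninjured_mean_405_488": self.uninjured_mean,
            "n_pos_injured": self.n_pos_injured,
            "n_neg_injured": self.n_neg_injured,
            "n_pos_uninjured": self.n_pos_uninjured,
            "n_neg_uninjured": self.n_neg_uninjured,
            "timepoint_h": self.timepoint_h,
        }
        if self.ci95 is not None:
            rows["ci95_lo"], rows["ci95_hi"] = self.ci95
        return pd.DataFrame({"value": rows})


def oxidation_ratio(
    injured: GatedCondition, uninjured: GatedCondition, per_event: bool = True
) -> OxidationResult:
    """Injured minus time-matched uninjured background-corrected 405/488 ratio."""
    if injured.condition.timepoint_h != uninjured.condition.timepoint_h:
        raise ValueError(
            "timepoint mismatch: oxidation is normalized to time-matched uninjured "
            f"controls ({injured.condition.timepoint_h} h vs {uninjured.condition.timepoint_h} h)"
        )
    inj_ratios, inj_mean = background_corrected_ratio(injured, per_event=per_event)
    uni_ratios, uni_mean = background_corrected_ratio(uninjured, per_event=per_event)
    return OxidationResult(
        oxidation_ratio=inj_mean - uni_mean,
        injured_mean=inj_mean,
        uninjured_mean=uni_mean,
        per_event_ratios=inj_ratios,
        uninjured_per_event_ratios=uni_ratios,
        n_pos_injured=injured.n_pos,
        n_neg_injured=injured.n_neg,
        n_pos_uninjured=uninjured.n_pos,
        n_neg_uninjured=uninjured.n_neg,
        timepoint_h=injured.condition.timepoint_h,
    )


@dataclass
class RetentionSummary:
    """Per-worm GFP retention of an injured population and its mean (the Δ)."""

    per_worm_retention: np.ndarray
    retention_delta: float
    n: int
    uninjured_mean_gfp: float


def gfp_retention(
    injured: WormPopulation | GatedCondition | Sequence[float],
    uninjured_mean_gfp: float,
    head_fraction: float = 0.20,
) -> RetentionSummary:
    """Per-worm GFP retention: head GFP peak over the mean uninjured head peak.

    ``injured`` may be a population (head peaks extracted, orienting profiles
    when present), a gated condition (its mCh+ events are used) or a bare
    sequence of head peaks.
    """
    if uninjured_mean_gfp <= 0:
        raise ValueError("uninjured mean GFP must be positive")
    if isinstance(injured, WormPopulation):
        injured.require_events(1)
        peaks = injured.head_peaks(head_fraction)
    elif isinstance(injured, GatedCondition):
        if injured.n_pos < 1:
            raise ValueError("no mCh+ events in injured condition")
        peaks = injured.mch_pos["gfp488_peak"].to_numpy(dtype=float)
    else:
        peaks = np.asarray(injured, dtype=float)
        if peaks.size < 1:
            raise ValueError("need at least one injured worm")
    retention = peaks / uninjured_mean_gfp
    return RetentionSummary(
        per_worm_retention=retention,
        retention_delta=float(retention.mean()),
        n=int(retention.size),
        uninjured_mean_gfp=float(uninjured_mean_gfp),
    )


@dataclass
class GfpIndexResult:
    """Dopaminergic GFP index comparing a test arm's injury loss to control's."""

    index: float
    control_delta: float
    test_delta: float
    ci95: tuple[float, float] | None = None
    n_control: int | None = None
    n_test: int | None = None
    n_boot: int | None = None

    def summary(self) -> pd.DataFrame:
        rows = {
            "gfp_index": self.index,
            "control_retention_delta": self.control_delta,
            "test_retention_delta": self.test_delta,
        }
        if self.ci95 is not None:
            rows["ci95_lo"], rows["ci95_hi"] = self.ci95
        if self.n_control is not None:
            rows["n_control"], rows["n_test"] = self.n_control, self.n_test
        if self.n_boot is not None:
            rows["n_bootstrap"] = self.n_boot
        return pd.DataFrame({"value": rows})


def dopaminergic_gfp_index(control_delta: float, test_delta: float) -> GfpIndexResult:
    """(controlΔ - testΔ) / (controlΔ - 1); >0 protective, <0 degenerative."""
    if control_delta == 1:
        raise ValueError("control shows no loss; index undefined (control_delta = 1)")
    index = (control_delta - test_delta) / (control_delta - 1.0)
    return GfpIndexResult(index=float(index), control_delta=control_delta, test_delta=test_delta)


def double_normalize(signal, background_mean: float, control_mean: float):
    """(signal - background) / (control - background).

    The generic two-step normalization used for sensor peak heights: first to
    non-transgenic background controls, then to time-matched uninjured
    transgenic controls. Background maps to 0 and the control mean to 1.
    """
    denom = control_mean - background_mean
    if denom <= 0:
        raise ValueError("control mean must exceed background mean")
    arr = np.asarray(signal, dtype=float)
    out = (arr - background_mean) / denom
    return float(out) if np.isscalar(signal) or arr.ndim == 0 else out


def aging_timecourse_normalize(
    populations: Sequence[WormPopulation],
    reference: tuple[str, float],
    head_fraction: float = 0.20,
) -> pd.DataFrame:
    """Mean head GFP per (arm, timepoint), normalized to one reference cell.

    ``reference`` is (arm, timepoint); the arm is the condition's rnai_or_drug
    label. The reference cell maps to exactly 1. Used for aging timecourses
    where every arm/day mean is expressed relative to, e.g., the control arm
    at day 3 of adulthood.
    """
    rows = []
    for pop in populations:
        pop.require_events(1)
        peaks = pop.head_peaks(head_fraction)
        rows.append(
            {
                "arm": pop.condition.rnai_or_drug,
                "timepoint_h": pop.condition.timepoint_h,
                "mean_gfp": float(np.mean(peaks)),
                "n": len(peaks),
            }
        )
    table = pd.DataFrame(rows)
    ref_arm, ref_t = reference
    ref_rows = table[(table["arm"] == ref_arm) & (table["timepoint_h"] == ref_t)]
    if len(ref_rows) == 0:
        raise ValueError(f"missing reference cell ({ref_arm!r}, {ref_t})")
    ref_mean = float(ref_rows["mean_gfp"].mean())
    if ref_mean <= 0:
        raise ValueError("reference cell mean must be positive")
    table["normalized"] = table["mean_gfp"] / ref_mean
    return table


# ---------------------------------------------------------------------------
# Model / Results interfaces


@dataclass
class OxidationModel:
    """Oxidation-ratio estimator over a gated injured/uninjured pair.

    ``fit`` computes the ratio and, when ``n_boot > 0``, a seeded bootstrap
    95% CI resampling worms within each of the four gated event sets.
    """

    injured: GatedCondition
    uninjured: GatedCondition
    per_event: bool = True

    def fit(self, n_boot: int = 2000, seed: int = 0) -> OxidationResult:
        res = oxidation_ratio(self.injured, self.uninjured, per_event=self.per_event)
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                boots[b] = (
                    oxidation_ratio(
                        _resample_gated(self.injured, rng),
                        _resample_gated(self.uninjured, rng),
                        per_event=self.per_event,
                    ).oxidation_ratio
                )
            res.ci95 = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
        return res


def _resample_gated(g: GatedCondition, rng: np.random.Generator) -> GatedCondition:
    return GatedCondition(
        mch_pos=g.mch_pos.sample(n=len(g.mch_pos), replace=True, random_state=_pdseed(rng)),
        mch_neg=g.mch_neg.sample(n=len(g.mch_neg), replace=True, random_state=_pdseed(rng)),
        threshold=g.threshold,
        condition=g.condition,
    )


def _pdseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


@dataclass
class GfpIndexModel:
    """GFP-index estimator over four worm populations.

    Built from the injured/uninjured pair of a control arm and of a test arm;
    ``fit`` estimates both retention deltas, the index, and a seeded bootstrap
    95% CI resampling worms within each of the four populations.
    """

    control_injured: WormPopulation
    control_uninjured: WormPopulation
    test_injured: WormPopulation
    test_uninjured: WormPopulation
    head_fraction: float = 0.20

    def _peaks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        hf = self.head_fraction
        return (
            self.control_injured.head_peaks(hf),
            self.control_uninjured.head_peaks(hf),
            self.test_injured.head_peaks(hf),
            self.test_uninjured.head_peaks(hf),
        )

    def fit(self, n_boot: int = 2000, seed: int = 0) -> GfpIndexResult:
        ci_peaks, cu_peaks, ti_peaks, tu_peaks = self._peaks()
        result = self._index(ci_peaks, cu_peaks, ti_peaks, tu_peaks)
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                boots[b] = self._index(
                    rng.choice(ci_peaks, ci_peaks.size),
                    rng.choice(cu_peaks, cu_peaks.size),
                    rng.choice(ti_peaks, ti_peaks.size),
                    rng.choice(tu_peaks, tu_peaks.size),
                ).index
            result.ci95 = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
            result.n_boot = n_boot
        result.n_control = ci_peaks.size
        result.n_test = ti_peaks.size
        return result

    def _index(self, ci, cu, ti, tu) -> GfpIndexResult:
        control = gfp_retention(ci, float(np.mean(cu)))
        test = gfp_retention(ti, float(np.mean(tu)))
        return dopaminergic_gfp_index(control.retention_delta, test.retention_delta)
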