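"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real experiments —
mosaic transgene carriage on a large-particle flow cytometer, injury-dependent
GFP retention and redox-sensor excitation shifts, RNAi DEG tables with
controlled overlap, qPCR plates with planted fold changes, and promoters with
planted motif sites — so that every downstream estimator can be tested against
planted truth without any external data.

Channel model: a strictly positive, right-skewed lognormal transgene signal
plus additive Gaussian autofluorescence truncated at zero. Worms that do not
carry the extrachromosomal array (mCherry-negative) show autofluorescence
only, in every channel. Oxidation is planted as a shift of the
background-corrected 405/488 ratio, i.e. in the same units the oxidation-ratio
estimator reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .flow import Condition, WormPopulation

__all__ = [
    "InjurySeverity",
    "PopulationParams",
    "DegSimParams",
    "PromoterSimParams",
    "KINETIC_TEMPLATES",
    "simulate_copas_population",
    "simulate_redox_timecourse",
    "simulate_axial_profiles",
    "simulate_deg_experiment",
    "simulate_promoters",
    "simulate_qpcr_plate",
    "simulate_tf_annotations",
]


@dataclass(frozen=True)
class InjurySeverity:
    """Provenance metadata for the blunt-force trauma protocol.

    Inert: carried on generated populations for provenance, never used in any
    computation. Defaults are the protocol's agitation settings.
    """

    duration_s: float = 16.0
    rpm: float = 8600.0


@dataclass
class PopulationParams:
    """Parameters of a simulated COPAS worm population.

    All fluorescence quantities are in arbitrary instrument units.
    ``true_retention`` multiplies the mean transgene GFP of injured carriers
    (1.0 = no loss); ``true_oxidation_shift`` is added to the
    background-corrected 405/488 ratio of injured carriers, on top of the
    reduced-sensor ``baseline_ratio``.
    """

    n_worms: int = 1000
    mosaic_rate: float = 0.6
    gfp488_log_mean: float = 5.0
    gfp488_log_sd: float = 0.4
    mcherry_log_mean: float = 4.0
    mcherry_log_sd: float = 0.5
    autofluor_mean_405: float = 1.0
    autofluor_mean_488: float = 2.0
    autofluor_mean_mcherry: float = 1.5
    autofluor_sd: float = 0.5
    baseline_ratio: float = 0.4
    true_retention: float = 1.0
    true_oxidation_shift: float = 0.0
    timepoint_h: float = 0.0
    injury_severity: InjurySeverity = field(default_factory=InjurySeverity)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        if not 0.0 < self.mosaic_rate <= 1.0:
            raise ValueError("mosaic_rate must be in (0, 1]")
        if not 0.0 < self.true_retention <= 1.0:
            raise ValueError("true_retention must be in (0, 1]")
        if self.true_oxidation_shift < 0:
            raise ValueError("true_oxidation_shift must be nonnegative")
        for name in ("gfp488_log_sd", "mcherry_log_sd", "autofluor_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class DegSimParams:
    """Parameters of a simulated two-perturbation differential-expression study."""

    n_genes: int = 1000
    n_true_cat1: int = 100
    n_true_cat2: int = 80
    overlap: int = 50
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.overlap > min(self.n_true_cat1, self.n_true_cat2):
            raise ValueError("overlap cannot exceed either true set size")
        if self.n_true_cat1 + self.n_true_cat2 - self.overlap > self.n_genes:
            raise ValueError("true sets exceed the gene universe")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be nonnegative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition (variance not estimable)")


@dataclass
class PromoterSimParams:
    """Parameters of simulated promoter windows with planted motif sites."""

    n_promoters: int = 20
    window_bp: int = 4000
    n_planted_sites: int = 3
    gc_content: float = 0.36  # roughly the C. elegans genome-wide GC fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_promoters < 1 or self.window_bp < 1:
            raise ValueError("n_promoters and window_bp must be positive")
        if self.n_planted_sites < 0:
            raise ValueError("n_planted_sites must be nonnegative")


# ---------------------------------------------------------------------------
# flow-cytometry populations


def simulate_copas_population(
    params: PopulationParams, condition: Condition | None = None
) -> WormPopulation:
    """Simulate one condition's worth of per-worm COPAS events.

    Each worm carries the extrachromosomal array with probability
    ``mosaic_rate``. Carriers draw a lognormal transgene GFP signal (scaled by
    ``true_retention`` when the condition is injured); their 405-channel signal
    is that GFP times the planted 405/488 ratio (baseline plus the oxidation
    shift when injured). Non-carriers show autofluorescence only. The returned
    population carries a ``truth`` sidecar (carrier flags and planted
    parameters) that is never part of the exported event table.
    """
    if condition is None:
        condition = Condition(treatment="uninjured", timepoint_h=params.timepoint_h)
    injured = condition.treatment == "injured"
    rng = np.random.default_rng(params.seed)
    n = params.n_worms

    carrier = rng.random(n) < params.mosaic_rate
    gfp = rng.lognormal(params.gfp488_log_mean, params.gfp488_log_sd, n)
    if injured:
        gfp = gfp * params.true_retention
    ratio = params.baseline_ratio + (params.true_oxidation_shift if injured else 0.0)
    mch = rng.lognormal(params.mcherry_log_mean, params.mcherry_log_sd, n)

    af405 = rng.normal(params.autofluor_mean_405, params.autofluor_sd, n)
    af488 = rng.normal(params.autofluor_mean_488, params.autofluor_sd, n)
    afmch = rng.normal(params.autofluor_mean_mcherry, params.autofluor_sd, n)

    gfp488 = np.clip(np.where(carrier, gfp, 0.0) + af488, 0.0, None)
    gfp405 = np.clip(np.where(carrier, gfp * ratio, 0.0) + af405, 0.0, None)
    mcherry = np.clip(np.where(carrier, mch, 0.0) + afmch, 0.0, None)
    extinction = rng.lognormal(6.0, 0.2, n)
    tof = rng.normal(1000.0, 80.0, n).clip(200.0, None)

    events = pd.DataFrame(
        {
            "worm_id": [f"w{i:05d}" for i in range(n)],
            "condition": condition.label,
            "treatment": condition.treatment,
            "timepoint_h": condition.timepoint_h,
            "replicate": condition.replicate,
            "extinction_peak": extinction,
            "tof": tof,
            "gfp488_peak": gfp488,
            "gfp405_peak": gfp405,
            "mcherry_peak": mcherry,
        }
    )
    truth = pd.DataFrame(
        {
            "worm_id": events["worm_id"],
            "carrier": carrier,
            "true_retention": params.true_retention if injured else 1.0,
            "true_oxidation_shift": params.true_oxidation_shift if injured else 0.0,
            "baseline_ratio": params.baseline_ratio,
        }
    )
    return WormPopulation(events=events, condition=condition, truth=truth)


#: Piecewise-linear kinetic templates (hours -> fraction of peak shift).
#: Qualitative emulations of compartment-specific redox kinetics: the
#: mitochondrial matrix responds within minutes and resolves by ~2 h, the outer
#: membrane peaks around 2 h, and the cytosol rises late and stays elevated
#: through 24-48 h. Configuration defaults, not fitted values.
KINETIC_TEMPLATES: dict[str, list[tuple[float, float]]] = {
    "matrix": [(0.0, 0.0), (0.083, 1.0), (2.0, 0.0), (48.0, 0.0)],
    "outer_membrane": [(0.0, 0.0), (2.0, 1.0), (24.0, 0.0), (48.0, 0.0)],
    "cytosolic": [(0.0, 0.0), (8.0, 0.3), (24.0, 1.0), (48.0, 1.0)],
}


def kinetic_shift(compartment: str, t_h: float, amplitude: float) -> float:
    """Planted oxidation shift at time ``t_h`` for a compartment template."""
    if compartment not in KINETIC_TEMPLATES:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of {sorted(KINETIC_TEMPLATES)}"
        )
    nodes = KINETIC_TEMPLATES[compartment]
    xs = [x for x, _ in nodes]
    ys = [y for _, y in nodes]
    return float(amplitude * np.interp(t_h, xs, ys))


def simulate_redox_timecourse(
    params: PopulationParams,
    timepoints_h: Sequence[float],
    compartment: str = "cytosolic",
) -> list[WormPopulation]:
    """One injured population per timepoint with a compartment-shaped shift.

    ``params.true_oxidation_shift`` is the template's peak amplitude; the
    planted shift at each timepoint is recorded in the population's truth
    sidecar (column ``true_oxidation_shift``).
    """
    if any(t < 0 for t in timepoints_h):
        raise ValueError("timepoints must be nonnegative")
    seeds = np.random.SeedSequence(params.seed).generate_state(len(timepoints_h)) % (2**31)
    out = []
    for t, sub_seed in zip(timepoints_h, seeds):
        shift = kinetic_shift(compartment, float(t), params.true_oxidation_shift)
        p_t = PopulationParams(
            **{
                **params.__dict__,
                "true_oxidation_shift": shift,
                "timepoint_h": float(t),
                "seed": int(sub_seed),
            }
        )
        cond = Condition(
            strain=f"sensor-{compartment}", treatment="injured", timepoint_h=float(t)
        )
        out.append(simulate_copas_population(p_t, cond))
    return out


def simulate_axial_profiles(
    n: int,
    n_bins: int = 50,
    head_at_start_prob: float = 0.5,
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Axial GFP profiles with a single dominant peak in the head-end 20%.

    Returns the profiles plus a truth table (head_at_start flag, peak bin in
    head-first orientation, peak value).
    """
    if n_bins < 5:
        raise ValueError("n_bins must be at least 5")
    rng = np.random.default_rng(seed)
    w = int(math.ceil(0.2 * n_bins))
    profiles: list[np.ndarray] = []
    rows = []
    for i in range(n):
        baseline = rng.uniform(0.0, 20.0, n_bins)
        peak_bin = int(rng.integers(0, w))
        peak_val = float(rng.lognormal(5.0, 0.3))  # ~150, well above baseline
        prof = baseline
        prof[peak_bin] = peak_val
        head_first = bool(rng.random() < head_at_start_prob)
        profiles.append(prof if head_first else prof[::-1].copy())
        rows.append({"head_at_start": head_first, "peak_bin": peak_bin, "peak_value": peak_val})
    return profiles, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential expression


def simulate_deg_experiment(params: DegSimParams):
    """Counts for a control group and two RNAi perturbations with planted DEGs.

    Genes 0..n_true_cat1-1 respond to the first perturbation; the second
    perturbation's responders are the first ``overlap`` of those plus the next
    ``n_true_cat2 - overlap`` genes. Per-gene counts follow a gamma-Poisson
    (negative-binomial) model with the planted log2 fold change applied to the
    perturbed group's mean. Returns ``(expr, truth)`` where ``expr`` is a
    :class:`dopaq.transcriptomics.ExpressionMatrix` over all three groups and
    ``truth`` maps set names to gene-id sets.
    """
    from .transcriptomics import ExpressionMatrix

    p = params
    rng = np.random.default_rng(p.seed)
    genes = [f"gene{i:05d}" for i in range(p.n_genes)]
    cat1_idx = set(range(p.n_true_cat1))
    cat2_idx = set(range(p.overlap)) | set(
        range(p.n_true_cat1, p.n_true_cat1 + (p.n_true_cat2 - p.overlap))
    )

    # moderately expressed genes only: planted effects must stay detectable
    # after RPKM pseudocounting, so baseline means are floored at 20 counts
    base_mu = rng.lognormal(math.log(500.0), 0.8, p.n_genes).clip(20.0, None)
    sign = rng.choice([-1.0, 1.0], size=p.n_genes)
    fc = 2.0 ** (sign * p.effect_log2fc)

    def draw(mu: np.ndarray, n_rep: int) -> np.ndarray:
        shape = 1.0 / p.dispersion
        lam = rng.gamma(shape, np.tile(mu, (n_rep, 1)) / shape)
        return rng.poisson(lam).T  # genes x replicates

    mu1 = base_mu.copy()
    mu1[list(cat1_idx)] *= fc[list(cat1_idx)]
    mu2 = base_mu.copy()
    mu2[list(cat2_idx)] *= fc[list(cat2_idx)]

    blocks = {
        "control": draw(base_mu, p.n_replicates),
        "cat1": draw(mu1, p.n_replicates),
        "cat2": draw(mu2, p.n_replicates),
    }
    counts = {}
    conditions = {}
    for cond, block in blocks.items():
        for r in range(p.n_replicates):
            name = f"{cond}_{r + 1}"
            counts[name] = block[:, r]
            conditions[name] = cond
    counts_df = pd.DataFrame(counts, index=genes)
    lengths = pd.Series(rng.integers(500, 5000, p.n_genes), index=genes, name="gene_length_bp")

    expr = ExpressionMatrix(counts=counts_df, gene_length_bp=lengths, sample_conditions=conditions)
    name = lambda idx: {genes[i] for i in idx}
    truth = {
        "cat1": name(cat1_idx),
        "cat2": name(cat2_idx),
        "cat1_only": name(cat1_idx - cat2_idx),
        "cat2_only": name(cat2_idx - cat1_idx),
        "both": name(cat1_idx & cat2_idx),
    }
    return expr, truth


# ---------------------------------------------------------------------------
# promoters


def simulate_promoters(params: PromoterSimParams, pwm) -> tuple[list[SeqRecord], pd.DataFrame]:
    """i.i.d.-background promoter windows with planted high-scoring motif sites.

    Sites are the PWM's consensus sequence (its maximum-scoring word), inserted
    at non-overlapping uniform positions on a uniform random strand. Returns
    FASTA records (id ``gene|tss|strand``) and a BED-like truth table
    (name, start, end, motif, score, strand; 0-based half-open).
    """
    p = params
    width = pwm.width
    if width > p.window_bp:
        raise ValueError("window_bp must be at least the motif width")
    rng = np.random.default_rng(p.seed)
    gc = p.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    consensus = pwm.consensus
    records: list[SeqRecord] = []
    rows = []
    for i in range(p.n_promoters):
        seq = rng.choice(alphabet, size=p.window_bp, p=probs)
        placed: list[int] = []
        for _ in range(p.n_planted_sites):
            pos = _place_nonoverlapping(rng, p.window_bp, width, placed)
            placed.append(pos)
            strand = "+" if rng.random() < 0.5 else "-"
            word = consensus if strand == "+" else str(Seq(consensus).reverse_complement())
            seq[pos : pos + width] = list(word)
            rows.append(
                {
                    "name": f"prom{i:03d}",
                    "start": pos,
                    "end": pos + width,
                    "motif": pwm.name,
                    "score": float(pwm.max_score),
                    "strand": strand,
                }
            )
        records.append(
            SeqRecord(
                Seq("".join(seq)),
                id=f"prom{i:03d}|{p.window_bp + 1}|+",
                description="synthetic promoter window",
            )
        )
    truth = pd.DataFrame(rows, columns=["name", "start", "end", "motif", "score", "strand"])
    return records, truth


def _place_nonoverlapping(rng, window_bp: int, width: int, placed: list[int]) -> int:
    for _ in range(1000):
        pos = int(rng.integers(0, window_bp - width + 1))
        if all(abs(pos - q) >= width for q in placed):
            return pos
    raise ValueError("cannot place planted sites without overlap")


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(
    fold_changes: Mapping[str, float],
    ref_ct: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    n_wells: int = 3,
    seed: int = 0,
    multi_peak_fraction: float = 0.0,
    reference_genes: Sequence[str] = ("tba-1", "Y45F10D.4"),
) -> pd.DataFrame:
    """Technical-replicate qPCR wells with planted fold changes.

    Two samples ("treated", "control"); each target gene's treated Ct is its
    baseline minus log2 of the planted fold. A ``multi_peak_fraction`` of wells
    is flagged with two melt peaks (off-target amplification) for the exclusion
    logic downstream. Returns a wells table (sample, gene, ct, melt_peaks).
    """
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
    ref_ct = dict(ref_ct or {})
    rng = np.random.default_rng(seed)
    genes = list(fold_changes) + [g for g in reference_genes if g not in fold_changes]
    rows = []
    for sample in ("treated", "control"):
        for gene in genes:
            base = ref_ct.get(gene, 20.0)
            fold = fold_changes.get(gene, 1.0) if sample == "treated" else 1.0
            for _ in range(n_wells):
                ct = base - math.log2(fold) + rng.normal(0.0, noise_sd)
                melt = 2 if rng.random() < multi_peak_fraction else 1
                rows.append({"sample": sample, "gene": gene, "ct": ct, "melt_peaks": melt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TF annotation tables


def simulate_tf_annotations(
    n_tfs: int = 60,
    n_passers: int = 12,
    rank_cutoff: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Annotation table with a planted set of full four-criterion passers.

    Every passer has rank within the cutoff, homologs in both mouse and worm,
    dopaminergic expression and at least one predicted promoter site; every
    non-passer fails at least one criterion. Returns the table and the planted
    passer names.
    """
    if n_passers > min(n_tfs, rank_cutoff):
        raise ValueError("cannot plant more passers than ranks within the cutoff")
    rng = np.random.default_rng(seed)
    names = [f"TF{i:03d}" for i in range(n_tfs)]
    ranks = rng.permutation(n_tfs) + 1
    in_cut = np.flatnonzero(ranks <= rank_cutoff)
    passers = set(rng.choice(in_cut, size=n_passers, replace=False).tolist())
    rows = []
    for i, name in enumerate(names):
        is_pass = i in passers
        mouse, worm, dopa = True, True, True
        sites = int(rng.integers(1, 9))
        if not is_pass:
            if ranks[i] <= rank_cutoff:
                # break one of the other criteria at random
                broken = rng.integers(0, 4)
                if broken == 0:
                    mouse = False
                elif broken == 1:
                    worm = False
                elif broken == 2:
                    dopa = False
                else:
                    sites = 0
            else:
                # outside the rank cutoff already fails; other flags arbitrary
                mouse = bool(rng.random() < 0.8)
                worm = bool(rng.random() < 0.8)
                dopa = bool(rng.random() < 0.6)
        rows.append(
            {
                "tf": name,
                "tft_rank": int(ranks[i]),
                "has_mouse_homolog": mouse,
                "has_worm_homolog": worm,
                "dopaminergic_expressed": dopa,
                "site_count": sites,
            }
        )
    return pd.DataFrame(rows), {names[i] for i in passers}
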