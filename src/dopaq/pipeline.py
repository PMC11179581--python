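"""Config-driven orchestration: simulate -> gate -> metrics -> stats -> reports.

A run is a pure function of (config, seed): every stage draws from a stream
deterministically derived from the single config seed, outputs carry a
provenance header (package version, seed, config hash), and rerunning the same
config yields byte-identical files. Filtering stages (outlier removal, well
exclusion) log kept + removed counts that always sum to their input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flow import (
    Condition,
    WormPopulation,
    estimate_gate_threshold,
    gate_mcherry,
    read_event_table,
    write_event_table,
)
from .metrics import GfpIndexModel, OxidationModel
from .robust import RoutConfig, compare_two, rout_clean
from .simulate import (
    DegSimParams,
    PopulationParams,
    PromoterSimParams,
    simulate_copas_population,
    simulate_deg_experiment,
    simulate_promoters,
    simulate_qpcr_plate,
    simulate_tf_annotations,
)
from .tfscreen import count_promoter_sites, filter_tf_candidates, read_jaspar, read_promoter_fasta
from .transcriptomics import (
    ExpressionMatrix,
    call_deg,
    cat1_specific_set,
    delta_delta_ct,
    hypergeometric_enrichment,
)

__all__ = ["RunConfig", "validate_config", "load_config", "run_pipeline", "demo_config_text"]

log = logging.getLogger("dopaq")

KNOWN_STAGES = ("simulate", "gate", "metrics", "stats", "degsets", "tfscreen")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "dopaq_run"
    stages: list[str] = field(default_factory=lambda: list(KNOWN_STAGES))
    # population / simulation
    n_worms: int = 800
    mosaic_rate: float = 0.6
    true_retention_control: float = 0.6
    true_retention_test: float = 0.9
    true_oxidation_shift: float = 0.5
    # metrics
    head_fraction: float = 0.20
    per_event: bool = True
    n_boot: int = 200
    # stats
    rout_q: float = 0.01
    # DEG simulation / calling
    n_genes: int = 1000
    n_true_cat1: int = 100
    n_true_cat2: int = 80
    overlap: int = 50
    effect_log2fc: float = 2.0
    n_replicates: int = 4
    deg_alpha: float = 0.05
    deg_min_abs_log2fc: float = 1.0
    # qPCR
    qpcr_fold_changes: dict = field(default_factory=lambda: {"cat-2": 4.0})
    # TF screen
    n_promoters: int = 10
    window_bp: int = 4000
    n_planted_sites: int = 3
    pwm_threshold: float = 0.8
    rank_cutoff: int = 50
    motifs_file: str | None = None  # None -> packaged demo motifs

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {stage!r}; known stages: {KNOWN_STAGES}")
        if not 0.0 < self.rout_q < 0.5:
            raise ValueError(f"rout_q must be in (0, 0.5), got {self.rout_q}")
        if not 0.0 < self.head_fraction <= 1.0:
            raise ValueError(f"head_fraction must be in (0, 1], got {self.head_fraction}")
        if not 0.0 < self.pwm_threshold <= 1.0:
            raise ValueError(f"pwm_threshold must be in (0, 1], got {self.pwm_threshold}")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config_text: str) -> RunConfig:
    """Parse and validate config text; unknown keys are rejected loudly."""
    raw = yaml.safe_load(config_text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())


def demo_config_text() -> str:
    """The packaged demo configuration."""
    return resources.files("dopaq.configs").joinpath("demo.yaml").read_text()


def _demo_motifs_text() -> str:
    return resources.files("dopaq.configs").joinpath("demo_motifs.jaspar").read_text()


# ---------------------------------------------------------------------------
# provenance-stamped table output


def write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dopaq {__version__}\n")
        fh.write(f"# seed={cfg.seed}\n")
        fh.write(f"# config_sha256={cfg.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# stages


def _stage_seeds(cfg: RunConfig) -> dict[str, int]:
    state = np.random.SeedSequence(cfg.seed).generate_state(len(KNOWN_STAGES)) % (2**31)
    return {stage: int(s) for stage, s in zip(KNOWN_STAGES, state)}


def _population_specs(cfg: RunConfig, seed: int):
    base = dict(n_worms=cfg.n_worms, mosaic_rate=cfg.mosaic_rate)
    sub = np.random.SeedSequence(seed).generate_state(6) % (2**31)
    return [
        ("control_injured", PopulationParams(**base, true_retention=cfg.true_retention_control,
                                             seed=int(sub[0])),
         Condition(strain="reporter", treatment="injured", rnai_or_drug="EV", timepoint_h=48.0)),
        ("control_uninjured", PopulationParams(**base, seed=int(sub[1])),
         Condition(strain="reporter", treatment="uninjured", rnai_or_drug="EV", timepoint_h=48.0)),
        ("test_injured", PopulationParams(**base, true_retention=cfg.true_retention_test,
                                          seed=int(sub[2])),
         Condition(strain="reporter", treatment="injured", rnai_or_drug="test", timepoint_h=48.0)),
        ("test_uninjured", PopulationParams(**base, seed=int(sub[3])),
         Condition(strain="reporter", treatment="uninjured", rnai_or_drug="test",
                   timepoint_h=48.0)),
        ("ox_injured", PopulationParams(**base, true_oxidation_shift=cfg.true_oxidation_shift,
                                        seed=int(sub[4])),
         Condition(strain="sensor", treatment="injured", rnai_or_drug="EV", timepoint_h=48.0)),
        ("ox_uninjured", PopulationParams(**base, seed=int(sub[5])),
         Condition(strain="sensor", treatment="uninjured", rnai_or_drug="EV", timepoint_h=48.0)),
    ]


def stage_simulate(cfg: RunConfig, out: Path, seed: int) -> None:
    events_dir = out / "events"
    events_dir.mkdir(parents=True, exist_ok=True)
    for name, params, cond in _population_specs(cfg, seed):
        pop = simulate_copas_population(params, cond)
        write_event_table(pop, events_dir / f"{name}.tsv")
        pop.truth.to_csv(events_dir / f"{name}.truth.tsv", sep="\t", index=False)
        log.info("simulate: %s n=%d", name, len(pop))

    sub = np.random.SeedSequence(seed + 1).generate_state(3) % (2**31)
    expr, truth = simulate_deg_experiment(
        DegSimParams(
            n_genes=cfg.n_genes, n_true_cat1=cfg.n_true_cat1, n_true_cat2=cfg.n_true_cat2,
            overlap=cfg.overlap, effect_log2fc=cfg.effect_log2fc,
            n_replicates=cfg.n_replicates, seed=int(sub[0]),
        )
    )
    deg_dir = out / "deg"
    deg_dir.mkdir(exist_ok=True)
    expr.counts.rename_axis("gene").to_csv(deg_dir / "counts.tsv", sep="\t")
    expr.gene_length_bp.rename_axis("gene").to_csv(deg_dir / "gene_lengths.tsv", sep="\t")
    pd.Series(expr.sample_conditions, name="condition").rename_axis("sample").to_csv(
        deg_dir / "sample_conditions.tsv", sep="\t"
    )
    with open(deg_dir / "truth_sets.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in truth.items()}, fh, indent=0, sort_keys=True)
    log.info("simulate: DEG counts %d genes x %d samples", *expr.counts.shape)

    plate = simulate_qpcr_plate(cfg.qpcr_fold_changes, noise_sd=0.15, seed=int(sub[1]),
                                multi_peak_fraction=0.05)
    write_table(plate, out / "qpcr" / "plate.tsv", cfg)
    log.info("simulate: qPCR plate %d wells", len(plate))

    motifs_text = (
        Path(cfg.motifs_file).read_text() if cfg.motifs_file else _demo_motifs_text()
    )
    (out / "tfscreen").mkdir(exist_ok=True)
    (out / "tfscreen" / "motifs.jaspar").write_text(motifs_text)
    pwms = read_jaspar(motifs_text)
    records, site_truth = simulate_promoters(
        PromoterSimParams(n_promoters=cfg.n_promoters, window_bp=cfg.window_bp,
                          n_planted_sites=cfg.n_planted_sites, seed=int(sub[2])),
        pwms[0],
    )
    from Bio import SeqIO

    with open(out / "tfscreen" / "promoters.fasta", "w") as fh:
        SeqIO.write(records, fh, "fasta")
    site_truth.to_csv(out / "tfscreen" / "sites_truth.bed", sep="\t", index=False, header=False)
    annotations, planted = simulate_tf_annotations(rank_cutoff=cfg.rank_cutoff, seed=int(sub[2]))
    write_table(annotations, out / "tfscreen" / "annotations.tsv", cfg)
    (out / "tfscreen" / "planted_passers.json").write_text(json.dumps(sorted(planted)))
    log.info("simulate: %d promoters, %d TF annotations", len(records), len(annotations))


def _load_populations(out: Path, names) -> dict[str, WormPopulation]:
    return {name: read_event_table(out / "events" / f"{name}.tsv") for name in names}


def stage_gate(cfg: RunConfig, out: Path, seed: int) -> None:
    rows = []
    for path in sorted((out / "events").glob("*.tsv")):
        if path.name.endswith(".truth.tsv"):
            continue
        pop = read_event_table(path)
        thr = estimate_gate_threshold(pop.events["mcherry_peak"])
        gated = gate_mcherry(pop, thr)
        assert gated.n_pos + gated.n_neg == len(pop)
        rows.append(
            {"population": path.stem, "threshold": thr, "n_pos": gated.n_pos,
             "n_neg": gated.n_neg, "n_total": len(pop)}
        )
        log.info("gate: %s threshold=%.4g n_pos=%d n_neg=%d (sum=%d in=%d)",
                 path.stem, thr, gated.n_pos, gated.n_neg, gated.n_pos + gated.n_neg, len(pop))
    write_table(pd.DataFrame(rows), out / "gating_summary.tsv", cfg)


def _gate(pop: WormPopulation):
    return gate_mcherry(pop, estimate_gate_threshold(pop.events["mcherry_peak"]))


def stage_metrics(cfg: RunConfig, out: Path, seed: int) -> None:
    pops = _load_populations(
        out, ["ox_injured", "ox_uninjured", "control_injured", "control_uninjured",
              "test_injured", "test_uninjured"]
    )
    ox = OxidationModel(_gate(pops["ox_injured"]), _gate(pops["ox_uninjured"]),
                        per_event=cfg.per_event).fit(n_boot=cfg.n_boot, seed=seed)
    write_table(ox.summary().rename_axis("quantity").reset_index(), out / "oxidation.tsv", cfg)
    log.info("metrics: oxidation_ratio=%.4f", ox.oxidation_ratio)

    gi = GfpIndexModel(
        control_injured=pops["control_injured"], control_uninjured=pops["control_uninjured"],
        test_injured=pops["test_injured"], test_uninjured=pops["test_uninjured"],
        head_fraction=cfg.head_fraction,
    ).fit(n_boot=cfg.n_boot, seed=seed + 1)
    write_table(gi.summary().rename_axis("quantity").reset_index(), out / "gfp_index.tsv", cfg)
    log.info("metrics: gfp_index=%.4f (controlD=%.4f testD=%.4f)",
             gi.index, gi.control_delta, gi.test_delta)


def stage_stats(cfg: RunConfig, out: Path, seed: int) -> None:
    pops = _load_populations(
        out, ["control_injured", "control_uninjured", "test_injured", "test_uninjured"]
    )
    rout = RoutConfig(q=cfg.rout_q)
    cleaned = {}
    rows = []
    for arm in ("control", "test"):
        inj = pops[f"{arm}_injured"].head_peaks(cfg.head_fraction)
        uni_mean = float(np.mean(pops[f"{arm}_uninjured"].head_peaks(cfg.head_fraction)))
        retention = inj / uni_mean
        res = rout_clean(retention, rout)
        assert len(res.kept) + res.n_removed == retention.size
        cleaned[arm] = res.kept
        rows.append(
            {"arm": arm, "n_in": retention.size, "n_kept": len(res.kept),
             "n_removed": res.n_removed, "rout_q": cfg.rout_q,
             "mean_retention": float(np.mean(res.kept))}
        )
        log.info("stats: ROUT %s kept=%d removed=%d (sum=%d in=%d)",
                 arm, len(res.kept), res.n_removed,
                 len(res.kept) + res.n_removed, retention.size)
    write_table(pd.DataFrame(rows), out / "rout_summary.tsv", cfg)
    test = compare_two(cleaned["test"], cleaned["control"], "test vs control retention")
    write_table(pd.DataFrame([test.as_row()]), out / "comparisons.tsv", cfg)
    log.info("stats: %s p=%.3g", test.comparison, test.p)


def stage_degsets(cfg: RunConfig, out: Path, seed: int) -> None:
    deg_dir = out / "deg"
    counts = pd.read_csv(deg_dir / "counts.tsv", sep="\t", index_col="gene")
    lengths = pd.read_csv(deg_dir / "gene_lengths.tsv", sep="\t", index_col="gene")[
        "gene_length_bp"
    ]
    conditions = pd.read_csv(deg_dir / "sample_conditions.tsv", sep="\t", index_col="sample")[
        "condition"
    ].to_dict()
    expr = ExpressionMatrix(counts=counts, gene_length_bp=lengths, sample_conditions=conditions)
    deg1 = call_deg(expr, ("cat1", "control"), cfg.deg_alpha, cfg.deg_min_abs_log2fc)
    deg2 = call_deg(expr, ("cat2", "control"), cfg.deg_alpha, cfg.deg_min_abs_log2fc)
    write_table(deg1, out / "deg_cat1.tsv", cfg)
    write_table(deg2, out / "deg_cat2.tsv", cfg)
    specific = cat1_specific_set(deg1, deg2)
    pd.Series(sorted(specific), name="gene").to_csv(out / "cat1_specific_genes.tsv",
                                                    sep="\t", index=False)
    log.info("degsets: %d cat1-specific genes", len(specific))

    truth = {k: set(v) for k, v in json.loads((deg_dir / "truth_sets.json").read_text()).items()}
    universe = set(counts.index)
    categories = {"planted_cat1_only": truth["cat1_only"], "planted_both": truth["both"],
                  "planted_cat2_only": truth["cat2_only"]}
    enrich = hypergeometric_enrichment(specific, categories, universe)
    write_table(enrich, out / "enrichment.tsv", cfg)

    plate = read_table(out / "qpcr" / "plate.tsv")
    n_excluded = int((plate["melt_peaks"] > 1).sum())
    qpcr = delta_delta_ct(plate, target_genes=sorted(cfg.qpcr_fold_changes))
    qpcr["n_wells_excluded_plate"] = n_excluded
    write_table(qpcr, out / "qpcr_folds.tsv", cfg)
    log.info("degsets: qPCR folds computed, %d multi-peak wells excluded (of %d)",
             n_excluded, len(plate))


def stage_tfscreen(cfg: RunConfig, out: Path, seed: int) -> None:
    tdir = out / "tfscreen"
    pwms = read_jaspar((tdir / "motifs.jaspar").read_text())
    windows = read_promoter_fasta(tdir / "promoters.fasta", window_bp=cfg.window_bp)
    rows = []
    for win in windows:
        counts = count_promoter_sites(win, pwms, cfg.pwm_threshold)
        for tf, n_sites in counts.items():
            rows.append({"promoter": win.gene, "tf": tf, "site_count": n_sites})
    write_table(pd.DataFrame(rows), out / "promoter_site_counts.tsv", cfg)
    annotations = read_table(tdir / "annotations.tsv")
    candidates = filter_tf_candidates(annotations, rank_cutoff=cfg.rank_cutoff)
    write_table(candidates, out / "tf_candidates.tsv", cfg)
    log.info("tfscreen: %d/%d TFs pass all four criteria",
             int(candidates["passed"].sum()), len(candidates))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "gate": stage_gate,
    "metrics": stage_metrics,
    "stats": stage_stats,
    "degsets": stage_degsets,
    "tfscreen": stage_tfscreen,
}


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Execute the configured stages in order; returns a small run report."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(cfg)
    report = {"stages_run": [], "seed": cfg.seed, "config_hash": cfg.config_hash}
    try:
        if not cfg.stages:
            log.warning("empty stage list: nothing to do")
            return report
        for stage in cfg.stages:
            log.info("stage %s: start", stage)
            try:
                _STAGE_FUNCS[stage](cfg, out, seeds[stage])
            except Exception:
                log.exception("stage %s: FAILED", stage)
                raise RuntimeError(f"pipeline failed in stage {stage!r}; see {out/'run.log'}")
            report["stages_run"].append(stage)
            log.info("stage %s: done", stage)
    finally:
        log.removeHandler(handler)
        handler.close()
    return report
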