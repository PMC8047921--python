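"""Synthetic LFQ cohorts with known ground truth.

Emulates the statistical structure of a postmortem pineal-gland label-free
proteomics study: ~18 control and 7 case subjects, two technical replicate
runs each, death times clustered into a day and a night group, thousands of
proteins with log2 LFQ baselines around 27, and missingness that is partly
intensity-dependent (left-censoring per run) and partly completely at
random.  Protein classes:

``null``            no group or time structure
``day_up_step``     +step/2 in day subjects, -step/2 in night subjects
``night_up_step``   the mirror image
``sinusoidal``      amplitude * cos(2*pi*(t_death - phase)/period), period
                    drawn uniformly in [23, 24] h
``only_day``/``only_night``  present at baseline, all replicates forced
                    missing in the opposite day/night condition
``only_control``    all replicates forced missing in case subjects

The generator writes the same TSV dialects the ingest module reads, so the
whole pipeline is exercisable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import LfqMatrix, SampleMeta, make_log_matrix

__all__ = ["SimConfig", "TruthTable", "generate", "inject_missingness",
           "write_dataset"]

CLASSES = ("null", "day_up_step", "night_up_step", "sinusoidal",
           "only_day", "only_night", "only_control")


@dataclass
class SimConfig:
    """Study-design and effect parameters of the synthetic cohort.

    Class fractions may sum to less than 1; the remainder is null.  Effect
    sizes are in log2 units.  ``censor_quantile`` is the per-run intensity
    quantile around which the left-censoring dropout probability is centred
    (0 disables censoring); ``censor_scale`` is the logistic width in log2
    units; ``mcar_rate`` adds uniform dropouts on top.
    """

    n_control: int = 18
    n_case: int = 7
    n_replicates: int = 2
    n_proteins: int = 2000
    fractions: dict = field(default_factory=lambda: {
        "day_up_step": 0.05,
        "night_up_step": 0.05,
        "sinusoidal": 0.05,
        "only_day": 0.05,
        "only_night": 0.05,
        "only_control": 0.02,
    })
    step_effect: float = 2.0
    sinusoid_amplitude: float = 2.0
    between_subject_sd: float = 0.5
    replicate_sd: float = 0.2
    baseline_mean: float = 27.0
    baseline_sd: float = 2.0
    censor_quantile: float = 0.05
    censor_scale: float = 0.5
    mcar_rate: float = 0.01
    death_time_scheme: str = "clustered"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown protein classes: {sorted(unknown)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(self.fractions.values()) > 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("between_subject_sd", "replicate_sd", "baseline_sd",
                     "censor_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("censor_quantile", "mcar_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.death_time_scheme not in ("clustered", "uniform"):
            raise ValueError("death_time_scheme must be 'clustered' or 'uniform'")


@dataclass
class TruthTable:
    """Ground-truth labels: one row per protein with class, effect size and
    (for sinusoidal proteins) period and phase."""

    table: pd.DataFrame


def _death_times(rng, daynight: np.ndarray, scheme: str) -> np.ndarray:
    """Autopsy-like death times: a midday and a small-hours cluster."""
    n = len(daynight)
    if scheme == "uniform":
        return rng.uniform(0, 24, n)
    centers = np.where(daynight == "day", 14.0, 2.0)
    return (centers + rng.normal(0, 2.5, n)) % 24


def generate(config: SimConfig) -> tuple[LfqMatrix, SampleMeta, TruthTable]:
    """Draw a complete synthetic cohort: raw-scale LFQ matrix (with
    missingness already injected), per-run metadata, ground-truth table.
    Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    # ---- subjects and runs ------------------------------------------------
    n_subj = config.n_control + config.n_case
    subject_ids = ([f"C{i + 1:02d}" for i in range(config.n_control)]
                   + [f"A{i + 1:02d}" for i in range(config.n_case)])
    groups = np.array(["control"] * config.n_control + ["autism"] * config.n_case)
    # balanced day/night split within each group
    daynight = np.empty(n_subj, dtype=object)
    for g in ("control", "autism"):
        idx = np.flatnonzero(groups == g)
        half = len(idx) // 2
        lab = np.array(["day"] * (len(idx) - half) + ["night"] * half)
        daynight[idx] = rng.permutation(lab)
    tod = _death_times(rng, daynight, config.death_time_scheme)

    rows = []
    for si, subj in enumerate(subject_ids):
        for r in range(config.n_replicates):
            rows.append({"run_id": f"{subj}_r{r + 1}", "subject_id": subj,
                         "group": groups[si], "daynight": daynight[si],
                         "time_of_death": round(float(tod[si]), 4)})
    meta = SampleMeta(pd.DataFrame(rows))

    # ---- protein classes --------------------------------------------------
    n_prot = config.n_proteins
    counts = {c: int(round(config.fractions.get(c, 0.0) * n_prot)) for c in CLASSES
              if c != "null"}
    if sum(counts.values()) > n_prot:
        raise ValueError("class fractions infeasible for n_proteins")
    labels = np.array(["null"] * n_prot, dtype=object)
    order = rng.permutation(n_prot)
    pos = 0
    for c in CLASSES:
        if c == "null":
            continue
        labels[order[pos:pos + counts[c]]] = c
        pos += counts[c]
    protein_ids = np.array([f"P{i + 1:05d}" for i in range(n_prot)])

    effect = np.zeros(n_prot)
    effect[np.isin(labels, ["day_up_step", "night_up_step"])] = config.step_effect
    sin_rows = labels == "sinusoidal"
    effect[sin_rows] = config.sinusoid_amplitude
    period = np.full(n_prot, np.nan)
    phase = np.full(n_prot, np.nan)
    period[sin_rows] = rng.uniform(23.0, 24.0, sin_rows.sum())
    phase[sin_rows] = rng.uniform(0.0, 24.0, sin_rows.sum())

    # ---- log2 signal ------------------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_prot)
    day_sign = np.where(daynight == "day", 0.5, -0.5)  # per subject
    subj_mean = np.tile(baseline[:, None], (1, n_subj))
    subj_mean[labels == "day_up_step"] += config.step_effect * day_sign
    subj_mean[labels == "night_up_step"] -= config.step_effect * day_sign
    if sin_rows.any():
        osc = config.sinusoid_amplitude * np.cos(
            2 * np.pi * (tod[None, :] - phase[sin_rows, None]) / period[sin_rows, None]
        )
        subj_mean[sin_rows] += osc
    subj_val = subj_mean + rng.normal(0, config.between_subject_sd, (n_prot, n_subj))

    run_cols, run_ids = [], []
    for si, subj in enumerate(subject_ids):
        for r in range(config.n_replicates):
            run_ids.append(f"{subj}_r{r + 1}")
            run_cols.append(subj_val[:, si]
                            + rng.normal(0, config.replicate_sd, n_prot))
    log2_vals = np.column_stack(run_cols)

    truth = TruthTable(pd.DataFrame({
        "protein_id": protein_ids, "class_label": labels,
        "effect_size": effect, "period": period, "phase": phase,
    }))

    complete = make_log_matrix(pd.DataFrame(log2_vals, index=pd.Index(protein_ids,
                               name="protein_id"), columns=run_ids))
    masked_log = inject_missingness(complete, config, rng, meta=meta, truth=truth)
    raw = LfqMatrix(pd.DataFrame(np.power(2.0, masked_log.intensity.to_numpy()),
                                 index=masked_log.intensity.index,
                                 columns=masked_log.intensity.columns))
    return raw, meta, truth


def inject_missingness(matrix: LfqMatrix, config: SimConfig,
                       rng: np.random.Generator,
                       meta: SampleMeta | None = None,
                       truth: TruthTable | None = None) -> LfqMatrix:
    """Apply left-censoring, MCAR dropouts and class-forced masks to a
    complete log-scale matrix.

    Left-censoring is run-specific: each run's dropout probability is a
    logistic function of log2 intensity centred at that run's
    ``censor_quantile`` quantile, width ``censor_scale``.  ``only_day`` /
    ``only_night`` proteins are fully masked in the opposite day/night
    condition and ``only_control`` proteins in case subjects (requires
    ``meta`` and ``truth``).
    """
    V = matrix.intensity.to_numpy(dtype=float).copy()
    n_prot, n_runs = V.shape
    if config.censor_quantile > 0:
        tau = np.nanquantile(V, config.censor_quantile, axis=0)
        with np.errstate(over="ignore"):
            p_drop = 1.0 / (1.0 + np.exp((V - tau[None, :]) / config.censor_scale))
        V[rng.random((n_prot, n_runs)) < p_drop] = np.nan
    if config.mcar_rate > 0:
        V[rng.random((n_prot, n_runs)) < config.mcar_rate] = np.nan

    if meta is not None and truth is not None:
        labels = truth.table.set_index("protein_id")["class_label"]
        lab = labels.loc[matrix.intensity.index].to_numpy()
        run_daynight = np.array([meta.subject_label(meta.table.set_index("run_id")
                                                    .loc[r, "subject_id"], "daynight")
                                 for r in matrix.run_ids])
        run_group = np.array([meta.subject_label(meta.table.set_index("run_id")
                                                 .loc[r, "subject_id"], "group")
                              for r in matrix.run_ids])
        V[np.ix_(lab == "only_day", np.flatnonzero(run_daynight == "night"))] = np.nan
        V[np.ix_(lab == "only_night", np.flatnonzero(run_daynight == "day"))] = np.nan
        V[np.ix_(lab == "only_control", np.flatnonzero(run_group != "control"))] = np.nan
    return make_log_matrix(pd.DataFrame(V, index=matrix.intensity.index,
                                        columns=matrix.intensity.columns))


def write_dataset(raw: LfqMatrix, meta: SampleMeta, truth: TruthTable,
                  config: SimConfig, outdir) -> None:
    """Write LFQ table (MaxQuant dialect), metadata, truth table and config."""
    from pathlib import Path

    from .io import write_lfq_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_lfq_table(raw, out / "lfq.tsv")
    meta.table.to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
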