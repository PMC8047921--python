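"""End-to-end day/night analysis: ingest -> three detectors -> consensus.

``run_day_night`` ties the pieces together the way the full study analysis
proceeds: log-normalize the LFQ matrix, run the Monte-Carlo day/night
contrast on replicate-level data, build subject-level series (one fixed-seed
imputation pass, then replicate averaging) for the two rhythmicity
detectors, intersect the three hit sets, and optionally project the
modulated/exclusive proteins onto a PPI graph.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .bgls import DEFAULT_CONCENTRATION_THRESHOLD
from .estimators import BglsDetector, JtkDetector, MonteCarloPresence
from .io import LfqMatrix, SampleMeta
from .network import project_and_summarize, venn_counts
from .presence import McConfig, write_calls

__all__ = ["subject_series", "run_day_night", "write_outputs"]


def subject_series(norm: LfqMatrix, meta: SampleMeta, seed: int = 0):
    """Subject-level series for the rhythm detectors.

    One imputation pass with a fixed seed: missing replicates of subjects
    with at least one observed replicate are drawn from the run-level
    normal fit, then replicates are averaged; fully missing subjects stay
    NaN.  Returns (proteins x subjects DataFrame, death-time array).
    """
    rng = np.random.default_rng(seed)
    subs = meta.subject_table()
    cols = {}
    V = norm.intensity
    stats = {}
    for r in V.columns:
        col = V[r].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            raise ValueError(f"run {r!r} has < 2 observed values")
        stats[r] = (obs.mean(), obs.std(ddof=1))
    for subj in subs["subject_id"]:
        runs = meta.replicate_runs(subj)
        block = V[runs].to_numpy(dtype=float)
        miss = np.isnan(block)
        any_obs = (~miss).any(axis=1)
        for kk, r in enumerate(runs):
            mu, sd = stats[r]
            cells = miss[:, kk] & any_obs
            block[cells, kk] = rng.normal(mu, sd, int(cells.sum()))
        vals = block.mean(axis=1)
        vals[~any_obs] = np.nan
        cols[subj] = vals
    df = pd.DataFrame(cols, index=V.index)
    times = subs.set_index("subject_id")["time_of_death"].loc[df.columns].to_numpy(float)
    return df, times


def run_day_night(raw: LfqMatrix, meta: SampleMeta, *, seed: int = 0,
                  n_sims: int = 2000, ppi_graph=None,
                  jtk_kwargs: dict | None = None,
                  bgls_kwargs: dict | None = None,
                  restrict_group: str | None = "control") -> dict:
    """Full day/night analysis; returns a dict of results tables/summaries.

    The day/night contrast and rhythm scans run on control subjects only by
    default (``restrict_group``), matching a design where cases are
    compared separately against controls.
    """
    if restrict_group is not None:
        meta_dn = meta.select(group=restrict_group)
    else:
        meta_dn = meta
    keep_runs = [r for r in raw.run_ids if r in set(meta_dn.run_ids)]
    norm = dio.log_normalize(LfqMatrix(raw.intensity[keep_runs]))

    mc = MonteCarloPresence(n_sims=n_sims, seed=seed,
                            contrast=("day", "night"), contrast_on="daynight")
    mc.fit(norm, meta_dn)

    series, times = subject_series(norm, meta_dn, seed=seed)
    testable = series.notna().sum(axis=1) >= 3
    series_t = series[testable]

    jtk = JtkDetector(seed=seed, **(jtk_kwargs or {}))
    jtk.fit(series_t, times)
    bgls = BglsDetector(**(bgls_kwargs or {}))
    bgls.fit(series_t, times)

    venn = venn_counts(jtk.flagged_, bgls.flagged_, mc.flagged_set())

    result = {
        "mc_calls": mc.calls_,
        "jtk_results": jtk.results_,
        "bgls_results": bgls.results_,
        "venn": venn,
        "mc_config": mc._config(),
    }
    if ppi_graph is not None:
        labels = _day_night_labels(mc.calls_)
        result["projection"] = project_and_summarize(ppi_graph, labels)
    return result


def _day_night_labels(calls: pd.DataFrame) -> dict:
    """Label modulated/exclusive proteins day or night by direction.

    Contrast side A is day: positive mean t or OnlyA -> "day", negative or
    OnlyB -> "night".
    """
    labels = {}
    for _, row in calls.iterrows():
        pid = _lead_symbol(row["protein_id"])
        if row["status"] == "OnlyA":
            labels[pid] = "day"
        elif row["status"] == "OnlyB":
            labels[pid] = "night"
        elif row["status"] == "Modulated" and row["significant"]:
            labels[pid] = "day" if row["t_mean"] > 0 else "night"
    return labels


def _lead_symbol(protein_id: str) -> str:
    """Lead gene symbol of a protein-group identifier ("SYM;SYM2|acc" -> SYM)."""
    return str(protein_id).split(";")[0].split("|")[0].strip().upper()


def write_outputs(result: dict, outdir) -> None:
    """Write deterministic TSV/YAML outputs of a ``run_day_night`` result."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_calls(result["mc_calls"], result["mc_config"], out / "mc_calls.tsv")
    result["jtk_results"].to_csv(out / "jtk.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    result["bgls_results"].to_csv(out / "bgls.tsv", sep="\t", index=False,
                                  float_format="%.10g")
    summary = {"venn": {k: int(v) for k, v in result["venn"].items()}}
    if "projection" in result:
        proj = result["projection"]
        summary["projection"] = {
            "n_nodes": proj.n_nodes,
            "n_edges": proj.n_edges,
            "n_components": proj.n_components,
            "fraction_in_largest_component": float(proj.fraction_in_largest_component),
            "label_fractions": {k: float(v) for k, v in proj.label_fractions.items()},
            "largest_component_label_fractions": {
                k: float(v) for k, v in proj.largest_component_label_fractions.items()},
        }
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
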