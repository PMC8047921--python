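"""Monte-Carlo presence/absence classification and differential abundance.

Label-free proteomics matrices are riddled with zeros that mean "not
quantified", concentrated among low-abundance proteins.  Rather than a
single imputation, the procedure here runs many stochastic imputations and
summarizes the resulting spread of test statistics:

1. Per subject, per protein: if every technical replicate is missing the
   subject is *missing* for that protein and nothing is imputed.  If some
   replicates are missing, each one is replaced by a draw from a normal
   distribution fitted to the mean and standard deviation of all observed
   log-LFQ values of that replicate run; the subject value is the mean of
   the replicate values.
2. Per subject: Z-score across the subject's non-missing proteins.
3. Per protein: count subjects with at least one observed replicate on each
   side of the contrast (day vs night, or control vs case).  Fewer than
   ``min_subjects`` on both sides -> ``Missing``; on exactly one side ->
   exclusive to the other side (``OnlyA``/``OnlyB``); otherwise
   ``Modulated`` and a two-sided Student t-test compares the subject
   Z-scores of the two sides.

Since imputation never changes which subjects are observed, the
classification is identical across simulations; only the t-test p-value
varies.  Across ``n_sims`` simulations the p-values are summarized by a
central percentile interval, and a protein is called significant when the
*upper* bound of that interval is below ``alpha`` — a deliberately
conservative rule.  Group-exclusive proteins get a bounded confidence score
instead of a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import LfqMatrix, SampleMeta

__all__ = [
    "McConfig",
    "PresencePattern",
    "STATUSES",
    "subject_average",
    "classify",
    "two_group_ttest",
    "confidence_score",
    "run_mc",
    "write_calls",
]

STATUSES = ("Missing", "OnlyA", "OnlyB", "Modulated")


@dataclass
class McConfig:
    """Settings of the Monte-Carlo contrast.

    contrast_on
        Metadata column holding the two group labels, ``"daynight"`` for the
        day/night contrast or ``"group"`` for control/case.
    contrast
        Pair (A, B) of labels in that column; ``OnlyA`` means present only
        on side A.
    test_values
        ``"zscore"`` (default) tests subject Z-scores; ``"log"`` tests the
        subject-averaged log intensities directly.
    confidence_variant
        Reading of the exclusive-presence confidence formula: ``"half"``
        (g = N_obs_absent / 2, default) or ``"squared"`` (g = N_obs_absent**2).
    """

    n_sims: int = 2000
    min_subjects: int = 3
    alpha: float = 0.05
    ci_level: float = 0.95
    seed: int = 0
    contrast: tuple[str, str] = ("day", "night")
    contrast_on: str = "daynight"
    equal_var: bool = True
    test_values: str = "zscore"
    confidence_variant: str = "half"

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.min_subjects < 1:
            raise ValueError("min_subjects must be >= 1")
        if self.test_values not in ("zscore", "log"):
            raise ValueError("test_values must be 'zscore' or 'log'")
        if self.confidence_variant not in ("half", "squared"):
            raise ValueError("confidence_variant must be 'half' or 'squared'")


@dataclass(frozen=True)
class PresencePattern:
    """Observed-subject counts per contrast side; a subject is observed when
    at least one of its replicates is non-missing.  Fixed across simulations."""

    n_obs_a: int
    n_tot_a: int
    n_obs_b: int
    n_tot_b: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_obs_a <= self.n_tot_a):
            raise ValueError("need 0 <= n_obs_a <= n_tot_a")
        if not (0 <= self.n_obs_b <= self.n_tot_b):
            raise ValueError("need 0 <= n_obs_b <= n_tot_b")


def subject_average(values, rng: np.random.Generator, replicate_stats) -> float:
    """Average a subject's replicate values, imputing missing replicates.

    ``replicate_stats`` is a sequence of (mean, sd) pairs, one per replicate
    run, fitted once on all observed log values of that run.  All replicates
    missing -> NaN (the subject stays missing; nothing is drawn).  With no
    missing replicate the result is deterministic.
    """
    vals = np.asarray(values, dtype=float)
    miss = np.isnan(vals)
    if miss.all():
        return float("nan")
    if miss.any():
        vals = vals.copy()
        for k in np.flatnonzero(miss):
            mu, sd = replicate_stats[k]
            vals[k] = rng.normal(mu, sd)
    return float(vals.mean())


def classify(pattern: PresencePattern, min_subjects: int = 3) -> str:
    """Presence/absence category from observed-subject counts.

    A side "has" the protein when at least ``min_subjects`` subjects observe
    it (the boundary count itself qualifies).  Neither side -> ``Missing``;
    one side -> ``OnlyA``/``OnlyB``; both -> ``Modulated``.
    """
    has_a = pattern.n_obs_a >= min_subjects
    has_b = pattern.n_obs_b >= min_subjects
    if has_a and has_b:
        return "Modulated"
    if has_a:
        return "OnlyA"
    if has_b:
        return "OnlyB"
    return "Missing"


def two_group_ttest(values_a, values_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student t-test (pooled variance by default).

    Degenerate zero-variance cases follow a declared convention rather than
    propagating NaN: equal means -> (0, 1); unequal means -> (+/-inf, 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        d = a.mean() - b.mean()
        if d == 0:
            return 0.0, 1.0
        return float(np.copysign(np.inf, d)), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def confidence_score(n_obs_i: int, n_tot_i: int, n_obs_j: int,
                     variant: str = "half") -> float:
    """Confidence that a protein is genuinely exclusive to the present side.

    ``i`` is the side where the protein is present (n_obs_i >= 3), ``j`` the
    side where it is essentially absent (n_obs_j < 3).  With
    f = (n_obs_i - 3)/(n_tot_i - 3) and g = n_obs_j / 2 (variant "half") or
    g = n_obs_j ** 2 (variant "squared"), the score is (f - g)/(f + g),
    defined as 0 when f + g = 0.  Bounded in [-1, 1]; increases with
    observations on the present side, decreases with stray observations on
    the absent side.
    """
    if n_tot_i <= 3:
        raise ValueError("confidence undefined for n_tot_i <= 3")
    f = (n_obs_i - 3) / (n_tot_i - 3)
    if variant == "half":
        g = n_obs_j / 2
    elif variant == "squared":
        g = float(n_obs_j) ** 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if f + g == 0:
        return 0.0
    return (f - g) / (f + g)


def _run_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-run (mean, sd) of observed log values; sd with ddof=1."""
    n = np.sum(~np.isnan(values), axis=0)
    if np.any(n < 2):
        raise ValueError("every run needs >= 2 non-missing proteins to fit "
                         "imputation statistics")
    mu = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    return mu, sd


def run_mc(norm: LfqMatrix, meta: SampleMeta, config: McConfig) -> pd.DataFrame:
    """Run the full Monte-Carlo contrast on a log-normalized matrix.

    Returns one row per protein: status, observed-subject pattern, mean t
    statistic, p-value interval bounds, significance flag and confidence
    score (exclusive proteins only).  Reproducible given ``config.seed``;
    per-simulation random substreams are derived from the simulation index
    so results do not depend on execution order.
    """
    la, lb = config.contrast
    sub = meta.subject_table()
    side = sub.set_index("subject_id")[config.contrast_on]
    subjects_a = [s for s in sub["subject_id"] if side[s] == la]
    subjects_b = [s for s in sub["subject_id"] if side[s] == lb]
    if not subjects_a or not subjects_b:
        raise ValueError(f"empty contrast group among {config.contrast}")
    subjects = subjects_a + subjects_b
    runs: list[str] = []
    run_subject: list[int] = []
    for si, s in enumerate(subjects):
        for r in meta.replicate_runs(s):
            runs.append(r)
            run_subject.append(si)
    run_subject_arr = np.asarray(run_subject)

    V = norm.intensity[runs].to_numpy(dtype=float)  # proteins x runs
    n_prot, n_runs = V.shape
    n_subj = len(subjects)
    mu_r, sd_r = _run_stats(V)

    miss = np.isnan(V)
    # subject observedness: at least one replicate observed
    obs = np.zeros((n_prot, n_subj), dtype=bool)
    for si in range(n_subj):
        obs[:, si] = (~miss[:, run_subject_arr == si]).any(axis=1)

    idx_a = np.arange(len(subjects_a))
    idx_b = np.arange(len(subjects_a), n_subj)
    n_obs_a = obs[:, idx_a].sum(axis=1)
    n_obs_b = obs[:, idx_b].sum(axis=1)
    m = config.min_subjects
    has_a, has_b = n_obs_a >= m, n_obs_b >= m
    status = np.where(has_a & has_b, "Modulated",
                      np.where(has_a, "OnlyA",
                               np.where(has_b, "OnlyB", "Missing")))
    mod = status == "Modulated"

    # fixed run-column -> subject mapping for fast averaging
    k_per_subj = np.bincount(run_subject_arr, minlength=n_subj).astype(float)

    n_missing_cells = int(miss.sum())
    miss_rows, miss_cols = np.nonzero(miss)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_sims)

    p_sims = np.empty((mod.sum(), config.n_sims))
    t_accum = np.zeros(mod.sum())
    na = n_obs_a[mod].astype(float)
    nb = n_obs_b[mod].astype(float)
    obs_mod = obs[mod]
    for s in range(config.n_sims):
        rng = np.random.default_rng(seeds[s])
        W = V.copy()
        if n_missing_cells:
            W[miss_rows, miss_cols] = (
                mu_r[miss_cols] + sd_r[miss_cols] * rng.standard_normal(n_missing_cells)
            )
        # subject average over all k replicate values (observed + imputed)
        subj_vals = np.zeros((n_prot, n_subj))
        for si in range(n_subj):
            subj_vals[:, si] = W[:, run_subject_arr == si].sum(axis=1) / k_per_subj[si]
        subj_vals[~obs] = np.nan

        if config.test_values == "zscore":
            mean_c = np.nanmean(subj_vals, axis=0)
            sd_c = np.nanstd(subj_vals, axis=0, ddof=1)
            X = (subj_vals - mean_c) / sd_c
        else:
            X = subj_vals

        Xm = X[mod]
        sum_a = np.nansum(np.where(obs_mod[:, idx_a], Xm[:, idx_a], 0.0), axis=1)
        sum_b = np.nansum(np.where(obs_mod[:, idx_b], Xm[:, idx_b], 0.0), axis=1)
        ma, mb = sum_a / na, sum_b / nb
        da = np.where(obs_mod[:, idx_a], Xm[:, idx_a] - ma[:, None], 0.0)
        db = np.where(obs_mod[:, idx_b], Xm[:, idx_b] - mb[:, None], 0.0)
        ssa = np.einsum("ij,ij->i", da, da)
        ssb = np.einsum("ij,ij->i", db, db)
        if config.equal_var:
            dof = na + nb - 2
            sp2 = (ssa + ssb) / dof
            se = np.sqrt(sp2 * (1 / na + 1 / nb))
        else:
            va_, vb_ = ssa / (na - 1), ssb / (nb - 1)
            se = np.sqrt(va_ / na + vb_ / nb)
            dof = se**4 / ((va_ / na) ** 2 / (na - 1) + (vb_ / nb) ** 2 / (nb - 1))
        diff = ma - mb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        # zero-variance conventions
        zero_se = se == 0
        t[zero_se & (diff == 0)] = 0.0
        t[zero_se & (diff != 0)] = np.copysign(np.inf, diff[zero_se & (diff != 0)])
        p = 2 * stats.t.sf(np.abs(t), dof)
        p[zero_se & (diff == 0)] = 1.0
        p[zero_se & (diff != 0)] = 0.0
        p_sims[:, s] = p
        t_accum += np.where(np.isfinite(t), t, np.copysign(1e30, t))

    tail = (1 - config.ci_level) / 2 * 100
    if config.n_sims == 1:
        p_low = p_high = p_sims[:, 0]
    else:
        p_low = np.percentile(p_sims, tail, axis=1)
        p_high = np.percentile(p_sims, 100 - tail, axis=1)
    t_mean = t_accum / config.n_sims

    n_tot_a, n_tot_b = len(subjects_a), len(subjects_b)
    out = pd.DataFrame({
        "protein_id": norm.protein_ids,
        "status": status,
        "n_obs_a": n_obs_a,
        "n_tot_a": n_tot_a,
        "n_obs_b": n_obs_b,
        "n_tot_b": n_tot_b,
        "t_mean": np.nan,
        "p_low": np.nan,
        "p_high": np.nan,
        "significant": False,
        "confidence": np.nan,
    })
    out.loc[mod, "t_mean"] = t_mean
    out.loc[mod, "p_low"] = p_low
    out.loc[mod, "p_high"] = p_high
    out.loc[mod, "significant"] = p_high < config.alpha
    for stat_label, present_idx in (("OnlyA", "a"), ("OnlyB", "b")):
        rows = status == stat_label
        if not rows.any():
            continue
        if present_idx == "a":
            oi, ti, oj = n_obs_a[rows], n_tot_a, n_obs_b[rows]
        else:
            oi, ti, oj = n_obs_b[rows], n_tot_b, n_obs_a[rows]
        out.loc[rows, "confidence"] = [
            confidence_score(int(a_), int(ti), int(b_), config.confidence_variant)
            for a_, b_ in zip(oi, oj)
        ]
    return out


def write_calls(calls: pd.DataFrame, config: McConfig, path) -> None:
    """Write the per-protein call table as TSV with the configuration echoed
    in a YAML comment header."""
    cfg = asdict(config)
    cfg["contrast"] = list(cfg["contrast"])
    header = "".join(
        f"# {line}\n" for line in yaml.safe_dump(cfg, sort_keys=True).splitlines()
    )
    with open(path, "w") as fh:
        fh.write(header)
        calls.to_csv(fh, sep="\t", index=False, float_format="%.10g")
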