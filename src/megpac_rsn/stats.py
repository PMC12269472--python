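"""Jackknife group statistics on RSN coupling-strength maps.

The sampling unit is the leave-one-out jackknife run: for a condition with N
usable subjects, the megPAC -> RSN chain is recomputed N times, omitting one
subject at a time. Each run's ten modes are matched to the condition's
template networks by the phi coefficient of the maps binarized at 40 % of
their maximum. Group comparisons are then mass-univariate (per-vertex two-way
ANOVA with medication and recording-session factors, Welch post-hoc,
Benjamini-Hochberg FDR), overlap tests against healthy-control templates
(Welch t, Bonferroni), and a three-way ANOVA of the per-run median
low-frequency component per network.

Leave-one-out runs of a cohort of N vary about (N-1) times less than
independent subject samples would; with ``jackknife_correction`` on (the
default), within-cell deviations of the run-level values are inflated by
(N-1) before any test, which restores subject-level sampling variance
(equivalently t / (N-1), F / (N-1)^2 in the balanced case).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .rsn import RSNSet, ReductionPlan, extract_rsns
from .simulate import CONDITIONS, condition_factors

__all__ = [
    "binarize_map",
    "phi_coefficient",
    "JackknifeEnsemble",
    "run_jackknife",
    "match_to_template",
    "match_ensemble",
    "MatchedRun",
    "welch_t",
    "student_t",
    "jackknife_inflate",
    "vertex_anova",
    "VertexStatsResult",
    "hc_overlap",
    "OverlapResult",
    "lowfreq_anova",
    "LowFreqResult",
    "POSTHOC_PAIRS",
]

logger = logging.getLogger(__name__)

#: Post-hoc contrasts of interest: medication within each session, session
#: within each medication state.
POSTHOC_PAIRS = (
    ("med@first", "first-OFF", "first-ON"),
    ("med@second", "second-OFF", "second-ON"),
    ("session@OFF", "first-OFF", "second-OFF"),
    ("session@ON", "first-ON", "second-ON"),
)

SESSION_PAIRS = ("session@OFF", "session@ON")


# ---------------------------------------------------------------------------
# binarization and phi


def binarize_map(map_values: np.ndarray, rel_threshold: float = 0.4) -> np.ndarray:
    """Vertices at or above ``rel_threshold`` * map maximum (inclusive)."""
    m = np.asarray(map_values, float)
    mx = m.max()
    if mx <= 0:
        raise ValueError("cannot binarize an all-zero map")
    return m >= rel_threshold * mx


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Phi coefficient of two binary maps (2x2 membership table).

    phi = (n11 n00 - n10 n01) / sqrt((n11+n10)(n01+n00)(n11+n01)(n10+n00)).
    Equals the Pearson correlation of the 0/1 vectors. A degenerate table
    (any zero marginal) returns 0 with a warning.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("maps must have the same vertex count")
    n11 = float(np.sum(a & b))
    n10 = float(np.sum(a & ~b))
    n01 = float(np.sum(~a & b))
    n00 = float(np.sum(~a & ~b))
    denom2 = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom2 == 0:
        warnings.warn("degenerate 2x2 table in phi coefficient; returning 0")
        return 0.0
    return (n11 * n00 - n10 * n01) / np.sqrt(denom2)


# ---------------------------------------------------------------------------
# jackknife ensembles and template matching


@dataclass(frozen=True)
class JackknifeEnsemble:
    """All leave-one-out RSN sets of one condition."""

    condition: str
    runs: tuple  # of (left_out_subject, RSNSet)

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def run_jackknife(series_by_subject: dict, plan: ReductionPlan,
                  n_modes: int = 10, condition: str = "first-OFF",
                  ) -> JackknifeEnsemble:
    """Leave-one-out RSN sets from per-subject (smoothed megPAC) series.

    Per-subject series are fixed inputs here (each subject's megPAC synthesis
    is independent of the rest of the group), so each run re-runs the group
    stage - concatenation, correlation, SVD, back-projection - on the N-1
    remaining subjects.
    """
    subjects = list(series_by_subject)
    if len(subjects) < 2:
        raise ValueError(
            f"jackknife needs >= 2 subjects, got {len(subjects)}"
        )
    runs = []
    for left_out in subjects:
        rest = {s: v for s, v in series_by_subject.items() if s != left_out}
        runs.append((left_out, extract_rsns(rest, plan, n_modes)))
    return JackknifeEnsemble(condition, tuple(runs))


@dataclass(frozen=True)
class MatchedRun:
    """One jackknife run's best-matching mode for one template network."""

    left_out: str
    mode_index: int
    phi: float
    map: np.ndarray  # (V,) coupling strength of the matched mode
    valid: bool = True


def match_to_template(rsns: RSNSet, template_map: np.ndarray,
                      rel_threshold: float = 0.4) -> tuple[int, float]:
    """Index and phi of the mode best matching the template.

    Both maps are binarized at ``rel_threshold`` of their maximum before phi.
    Ties break toward the lowest mode index. If phi is degenerate (<= 0) for
    every mode the match is invalid; callers should exclude the run.
    """
    tb = binarize_map(template_map, rel_threshold)
    phis = np.full(rsns.n_modes, -np.inf)
    for i in range(rsns.n_modes):
        mode = rsns.modes[i]
        if mode.max() <= 0:
            phis[i] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            phis[i] = phi_coefficient(binarize_map(mode, rel_threshold), tb)
    best = int(np.argmax(phis))
    return best, float(phis[best])


def assign_modes(rsns: RSNSet, templates: dict,
                 rel_threshold: float = 0.4) -> dict:
    """Exclusive template -> mode assignment for one RSN set.

    Greedy on descending phi (maps binarized at ``rel_threshold``): the
    globally best (template, mode) pair is fixed first and that mode is
    removed from the pool, so two templates can never claim the same mode.
    Returns {template name: (mode index, phi)}.
    """
    names = list(templates)
    phis = np.full((len(names), rsns.n_modes), -np.inf)
    for i, name in enumerate(names):
        tb = binarize_map(np.asarray(templates[name], float), rel_threshold)
        for j in range(rsns.n_modes):
            mode = rsns.modes[j]
            if mode.max() <= 0:
                phis[i, j] = 0.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                phis[i, j] = phi_coefficient(
                    binarize_map(mode, rel_threshold), tb
                )
    out: dict[str, tuple] = {}
    open_rows = set(range(len(names)))
    open_cols = set(range(rsns.n_modes))
    while open_rows and open_cols:
        best = max(
            ((i, j) for i in open_rows for j in open_cols),
            key=lambda ij: (phis[ij], -ij[1]),
        )
        i, j = best
        out[names[i]] = (j, float(phis[i, j]))
        open_rows.discard(i)
        open_cols.discard(j)
    return out


def match_ensemble(ensemble: JackknifeEnsemble, templates: dict,
                   rel_threshold: float = 0.4) -> dict:
    """Match every run of an ensemble to each template network.

    ``templates`` maps network name -> template map. Within each run the
    templates are assigned to *distinct* modes (greedy by descending phi):
    the analysed networks are different RSNs by construction, so one mode
    cannot stand for two of them. Returns {network: [MatchedRun, ...]};
    degenerate matches are flagged invalid and logged (callers drop them
    from the statistics).
    """
    out: dict[str, list] = {name: [] for name in templates}
    for left_out, rsns in ensemble.runs:
        assignment = assign_modes(rsns, templates, rel_threshold)
        for name in templates:
            idx, phi = assignment[name]
            valid = phi > 0
            if not valid:
                logger.warning(
                    "condition %s, run without %s: no mode matches template "
                    "%s (phi <= 0); excluding run",
                    ensemble.condition, left_out, name,
                )
            out[name].append(
                MatchedRun(left_out, idx, phi, rsns.modes[idx], valid)
            )
    return out


# ---------------------------------------------------------------------------
# test primitives


def jackknife_inflate(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Inflate within-cell deviations of leave-one-out values by (N - 1)."""
    v = np.asarray(values, float)
    n = v.shape[axis]
    mean = v.mean(axis=axis, keepdims=True)
    return mean + (n - 1) * (v - mean)


def welch_t(x: np.ndarray, y: np.ndarray):
    """Two-tailed Welch (unequal-variance) t-test along axis 0.

    Returns (t, df, p); works element-wise for 2-D (n, V) inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    zero = se2 == 0
    if np.ndim(t) == 0:
        if zero:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            df = float(n1 + n2 - 2)
    else:
        with np.errstate(invalid="ignore"):
            t = np.where(zero,
                         np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
        df = np.where(zero, float(n1 + n2 - 2), df)
    p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    return t, df, p


def student_t(x: np.ndarray, y: np.ndarray):
    """Two-tailed pooled-variance t-test along axis 0: (t, df, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.shape[0], y.shape[0]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(axis=0, ddof=1)
           + (n2 - 1) * y.var(axis=0, ddof=1)) / df
    diff = x.mean(axis=0) - y.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore"):
        t = np.where(sp2 == 0,
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    if np.ndim(t) == 0:
        t = float(t)
    p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    return t, float(df), p


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of y (n, V) under an orthonormal basis q."""
    return np.sum(y * y, axis=0) - np.sum((q.T @ y) ** 2, axis=0)


def twoway_anova_type2(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict:
    """Vectorized two-way ANOVA (Type II sums of squares) with interaction.

    Parameters
    ----------
    y : (n_obs, V) responses (V independent ANOVAs)
    a, b : (n_obs,) binary factor codes (medication, session)

    Returns a dict with per-effect F and p arrays plus sums of squares.
    Unbalanced designs are handled by the Type II model comparisons.
    """
    y = np.atleast_2d(np.asarray(y, float))
    n = y.shape[0]
    one = np.ones(n)
    ab = a * b
    q = {
        "full": np.linalg.qr(np.column_stack([one, a, b, ab]))[0],
        "add": np.linalg.qr(np.column_stack([one, a, b]))[0],
        "a": np.linalg.qr(np.column_stack([one, a]))[0],
        "b": np.linalg.qr(np.column_stack([one, b]))[0],
    }
    rss = {k: _rss(v, y) for k, v in q.items()}
    ss = {
        "A": np.clip(rss["b"] - rss["add"], 0.0, None),
        "B": np.clip(rss["a"] - rss["add"], 0.0, None),
        "A:B": np.clip(rss["add"] - rss["full"], 0.0, None),
    }
    sse = np.clip(rss["full"], 0.0, None)
    df_e = n - 4
    scale = np.sum(y * y, axis=0) + 1e-300
    eps = 1e-12 * scale
    out = {"sse": sse, "df_error": df_e, "ss": ss}
    for eff, ss_e in ss.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_e / 1.0) / (sse / df_e)
            p = sp_stats.f.sf(f, 1, df_e)
        degenerate = sse < eps
        f = np.where(degenerate, np.where(ss_e < eps, 0.0, np.inf), f)
        p = np.where(degenerate, np.where(ss_e < eps, 1.0, 0.0), p)
        out[f"F_{eff}"] = f
        out[f"p_{eff}"] = p
    return out


def _fdr_bh(pvals: np.ndarray, q: float) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if pvals.size == 0:
        return np.zeros(0, bool)
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# vertex-wise factorial statistics


@dataclass
class VertexStatsResult:
    """Mass-univariate results for one template network."""

    network: str
    included: np.ndarray           # (V,) bool inclusion mask
    anova_F: dict = field(default_factory=dict)   # effect -> (V,) (NaN outside)
    anova_p: dict = field(default_factory=dict)
    posthoc: dict = field(default_factory=dict)   # pair -> {t, df, p, sign}
    fdr_significant: dict = field(default_factory=dict)  # pair -> (V,) bool
    correction_scope: str = ""

    def significant_session_vertices(self) -> np.ndarray:
        """Vertices flagged in either session contrast after FDR."""
        out = np.zeros_like(self.included)
        for pair in SESSION_PAIRS:
            if pair in self.fdr_significant:
                out |= self.fdr_significant[pair]
        return out


def _stack_condition_values(matched: dict, network: str):
    """Run-level map values per condition: {cond: (n_runs, V)} (valid runs)."""
    values = {}
    for cond in CONDITIONS:
        rows = [r.map for r in matched[cond][network] if r.valid]
        if not rows:
            raise ValueError(f"no valid runs for {network} in {cond}")
        values[cond] = np.vstack(rows)
    return values


def vertex_anova(matched: dict, templates_by_condition: dict,
                 rel_threshold: float = 0.4, correction: bool = True,
                 fdr_q: float = 0.05) -> dict:
    """Per-vertex two-way ANOVA + Welch post-hoc + FDR for each network.

    Parameters
    ----------
    matched : {condition: {network: [MatchedRun]}} over all four conditions
    templates_by_condition : {condition: {network: template map}}; a vertex
        enters a network's analysis if it reaches ``rel_threshold`` of the
        map maximum in at least one condition's template.
    correction : apply the jackknife variance correction (see module docs).
    fdr_q : Benjamini-Hochberg level for the single family spanning
        vertices x networks x post-hoc comparisons.

    Returns {network: VertexStatsResult}.
    """
    missing = [c for c in CONDITIONS if c not in matched]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    networks = list(next(iter(matched.values())).keys())
    scope = (
        "jackknife variance correction on (within-cell deviations x (N-1))"
        if correction else "uncorrected run-level tests"
    )

    results: dict[str, VertexStatsResult] = {}
    family_p: list[np.ndarray] = []
    family_key: list[tuple] = []  # (network, pair, vertex_indices)

    for net in networks:
        values = _stack_condition_values(matched, net)
        n_v = values[CONDITIONS[0]].shape[1]
        included = np.zeros(n_v, bool)
        for cond in CONDITIONS:
            tmap = np.asarray(templates_by_condition[cond][net], float)
            included |= tmap >= rel_threshold * tmap.max()
        # drop vertices with zero variance in every cell
        allzero = np.ones(n_v, bool)
        for cond in CONDITIONS:
            allzero &= values[cond].std(axis=0) == 0
        n_skipped = int(np.sum(included & allzero))
        if n_skipped:
            logger.info(
                "%s: skipping %d included vertices with zero variance in all "
                "cells", net, n_skipped,
            )
        included &= ~allzero

        corrected = {
            cond: (jackknife_inflate(v) if correction else v)
            for cond, v in values.items()
        }
        y = np.vstack([corrected[c][:, included] for c in CONDITIONS])
        med = np.concatenate([
            np.full(corrected[c].shape[0],
                    1.0 if condition_factors(c)[1] == "ON" else 0.0)
            for c in CONDITIONS
        ])
        sess = np.concatenate([
            np.full(corrected[c].shape[0],
                    1.0 if condition_factors(c)[0] == "second" else 0.0)
            for c in CONDITIONS
        ])
        an = twoway_anova_type2(y, med, sess)

        res = VertexStatsResult(net, included, correction_scope=scope)
        eff_names = {"A": "medication", "B": "session", "A:B": "interaction"}
        for key, name in eff_names.items():
            F = np.full(n_v, np.nan)
            p = np.full(n_v, np.nan)
            F[included] = an[f"F_{key}"]
            p[included] = an[f"p_{key}"]
            res.anova_F[name] = F
            res.anova_p[name] = p

        for pair_name, c1, c2 in POSTHOC_PAIRS:
            t, df, p = welch_t(corrected[c1][:, included],
                               corrected[c2][:, included])
            tf = np.full(n_v, np.nan)
            dff = np.full(n_v, np.nan)
            pf = np.full(n_v, np.nan)
            sg = np.full(n_v, np.nan)
            tf[included], dff[included], pf[included] = t, df, p
            sg[included] = np.sign(
                values[c1][:, included].mean(axis=0)
                - values[c2][:, included].mean(axis=0)
            )
            res.posthoc[pair_name] = {"t": tf, "df": dff, "p": pf, "sign": sg}
            family_p.append(p)
            family_key.append((net, pair_name, np.nonzero(included)[0]))
        results[net] = res

    flat_p = np.concatenate(family_p) if family_p else np.zeros(0)
    reject = _fdr_bh(flat_p, fdr_q)
    pos = 0
    for (net, pair_name, v_idx), p_arr in zip(family_key, family_p):
        k = p_arr.size
        mask = np.zeros(results[net].included.size, bool)
        mask[v_idx] = reject[pos:pos + k]
        results[net].fdr_significant[pair_name] = mask
        pos += k
    return results


# ---------------------------------------------------------------------------
# healthy-control overlap


@dataclass
class OverlapResult:
    """Phi overlap of jackknife RSNs with external (healthy-control) maps."""

    runs: pd.DataFrame     # network, condition, left_out, phi
    summary: pd.DataFrame  # network, condition, mean, sd, n  (raw values)
    tests: pd.DataFrame    # pairwise t-tests with Bonferroni correction


def hc_overlap(matched: dict, hc_templates: dict,
               rel_threshold: float = 0.4, correction: bool = True,
               alpha: float = 0.05) -> OverlapResult:
    """Per-run phi against healthy-control templates + pairwise tests.

    Both the matched jackknife map and the control template are binarized at
    ``rel_threshold`` of their maximum before phi. Pairwise two-tailed tests
    between the four conditions (Welch by default; Student statistics are
    reported alongside) are Bonferroni-corrected over the 6 condition pairs
    x number of networks.
    """
    run_rows = []
    vectors: dict[tuple, np.ndarray] = {}
    for net, template in hc_templates.items():
        tb = binarize_map(np.asarray(template, float), rel_threshold)
        for cond in CONDITIONS:
            phis = []
            for r in matched[cond][net]:
                if not r.valid:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ph = phi_coefficient(
                        binarize_map(r.map, rel_threshold), tb
                    )
                phis.append(ph)
                run_rows.append(
                    {"network": net, "condition": cond,
                     "left_out": r.left_out, "phi": ph}
                )
            vectors[(net, cond)] = np.asarray(phis)

    runs = pd.DataFrame(run_rows)
    summary = (
        runs.groupby(["network", "condition"])["phi"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )

    pairs = list(itertools.combinations(CONDITIONS, 2))
    m = len(pairs) * len(hc_templates)
    test_rows = []
    for net in hc_templates:
        for c1, c2 in pairs:
            x = vectors[(net, c1)]
            y = vectors[(net, c2)]
            if correction:
                x = jackknife_inflate(x)
                y = jackknife_inflate(y)
            tw, dfw, pw = welch_t(x[:, None], y[:, None])
            ts, dfs, ps = student_t(x[:, None], y[:, None])
            p_bonf = min(1.0, float(pw[0]) * m)
            test_rows.append({
                "network": net, "cond1": c1, "cond2": c2,
                "t_welch": float(tw[0]), "df_welch": float(dfw[0]),
                "p_welch": float(pw[0]),
                "t_student": float(np.asarray(ts).ravel()[0]),
                "df_student": dfs,
                "p_student": float(np.asarray(ps).ravel()[0]),
                "p_bonferroni": p_bonf,
                "significant": p_bonf < alpha,
            })
    return OverlapResult(runs, summary, pd.DataFrame(test_rows))


# ---------------------------------------------------------------------------
# low-frequency component


@dataclass
class LowFreqResult:
    """Three-way ANOVA of per-run median max-coupling phase frequencies."""

    medians: pd.DataFrame  # condition, session, medication, network, run, median_fphi
    anova: pd.DataFrame    # effect, sum_sq, df, F, p, eta2_partial
    posthoc: pd.DataFrame  # pairwise level comparisons of significant effects


def lowfreq_anova(freq_maps: dict, matched: dict,
                  rel_threshold: float = 0.4, correction: bool = True,
                  alpha: float = 0.05) -> LowFreqResult:
    """Median best phase frequency per (run, network, condition) + 3-way ANOVA.

    Parameters
    ----------
    freq_maps : {condition: {left_out_subject: (V,) best-phase-frequency map}}
        of the jackknife runs (per-run vertex frequency = aggregate of the
        run's subjects; computed by the pipeline).
    matched : {condition: {network: [MatchedRun]}}; a run's network membership
        mask is its matched map binarized at ``rel_threshold``.
    """
    rows = []
    for cond in CONDITIONS:
        session, med = condition_factors(cond)
        nets = matched[cond]
        for net, runs in nets.items():
            for r in runs:
                if not r.valid:
                    continue
                if r.left_out not in freq_maps[cond]:
                    continue
                if r.map.max() <= 0:
                    logger.warning(
                        "%s/%s run %s: empty map; excluded", cond, net,
                        r.left_out,
                    )
                    continue
                mask = binarize_map(r.map, rel_threshold)
                if not mask.any():
                    logger.warning(
                        "%s/%s run %s: empty RSN mask; excluded",
                        cond, net, r.left_out,
                    )
                    continue
                fmap = np.asarray(freq_maps[cond][r.left_out], float)
                rows.append({
                    "condition": cond, "session": session, "medication": med,
                    "network": net, "left_out": r.left_out,
                    "median_fphi": float(np.median(fmap[mask])),
                })
    medians = pd.DataFrame(rows)
    if medians.empty:
        raise ValueError("no usable (run, network) medians")

    df = medians.copy()
    df["value"] = df["median_fphi"]
    if correction:
        def _inflate(group):
            g = group.copy()
            g["value"] = jackknife_inflate(g["value"].to_numpy())
            return g
        df = (
            df.groupby(["condition", "network"], group_keys=False)[df.columns]
            .apply(_inflate)
        )

    anova = _threeway_anova(df)
    posthoc = _bonferroni_posthoc(df, anova, alpha)
    return LowFreqResult(medians, anova, posthoc)


def _threeway_anova(df: pd.DataFrame) -> pd.DataFrame:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(
        "value ~ C(network) * C(medication) * C(session)", data=df
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # harmless df warnings on degenerate fits
        table = sm.stats.anova_lm(model, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    scale = float(df["value"].pow(2).sum()) + 1e-300
    eps = 1e-12 * scale
    rows = []
    for effect, row in table.iterrows():
        if effect == "Residual":
            continue
        ss = float(row["sum_sq"])
        F = row["F"]
        p = row["PR(>F)"]
        if resid_ss < eps:  # degenerate: no residual variance
            F = 0.0 if ss < eps else np.inf
            p = 1.0 if ss < eps else 0.0
        if ss < eps and resid_ss < eps:
            eta2p = 0.0
        else:
            eta2p = ss / (ss + resid_ss) if (ss + resid_ss) > 0 else 0.0
        rows.append({
            "effect": effect.replace("C(", "").replace(")", ""),
            "sum_sq": ss, "df": float(row["df"]),
            "F": float(F), "p": float(p), "eta2_partial": float(eta2p),
        })
    rows.append({
        "effect": "Residual", "sum_sq": resid_ss,
        "df": float(table.loc["Residual", "df"]),
        "F": np.nan, "p": np.nan, "eta2_partial": np.nan,
    })
    return pd.DataFrame(rows)


def _bonferroni_posthoc(df: pd.DataFrame, anova: pd.DataFrame,
                        alpha: float) -> pd.DataFrame:
    factors = {"network": "network", "medication": "medication",
               "session": "session"}
    rows = []
    sig_effects = set(
        anova.loc[(anova["p"] < alpha) & anova["effect"].isin(factors),
                  "effect"]
    )
    comparisons = []
    for eff in sig_effects:
        col = factors[eff]
        for l1, l2 in itertools.combinations(sorted(df[col].unique()), 2):
            comparisons.append((eff, col, l1, l2))
    m = len(comparisons)
    for eff, col, l1, l2 in comparisons:
        x = df.loc[df[col] == l1, "value"].to_numpy()
        y = df.loc[df[col] == l2, "value"].to_numpy()
        t, dof, p = welch_t(x[:, None], y[:, None])
        rows.append({
            "effect": eff, "level1": l1, "level2": l2,
            "t": float(t[0]), "df": float(dof[0]), "p": float(p[0]),
            "p_bonferroni": min(1.0, float(p[0]) * m),
        })
    return pd.DataFrame(
        rows, columns=["effect", "level1", "level2", "t", "df", "p",
                       "p_bonferroni"],
    )
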