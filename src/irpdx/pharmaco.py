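"""Dose-response AUC, Loewe-additivity synergy, and drug-candidate ranking.

Viability is expressed throughout in % of vehicle control.  Monotherapy
curves are fitted with a four-parameter Hill model

    E(d) = Einf + (E0 - Einf) / (1 + (d / EC50)^h)

whose inverse D(E) is available in closed form.  The Loewe-additive
expectation at a dose pair (d1, d2) is the effect E solving

    d1 / D_a(E) + d2 / D_b(E) = 1

found by bracketed root-finding inside the achievable effect range.  The
synergy score is expected minus observed viability, so positive scores
mean synergy (more kill than dose additivity predicts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: p-adjusted threshold and fold-change floor defining "upregulated".
UPREG_ALPHA = 0.05
UPREG_LFC = 0.0


@dataclass
class DoseGrid:
    """A combination viability experiment.

    ``viability`` has shape (n_replicates, len(doses_a), len(doses_b));
    row/column 0 (dose 0) are the monotherapies of the other drug.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if v.ndim == 2:
            v = v[None]
        self.viability = v
        for doses in (self.doses_a, self.doses_b):
            if (doses < 0).any() or (np.diff(doses) <= 0).any():
                raise ValueError("doses must be non-negative and strictly increasing")
            if doses[0] != 0:
                raise ValueError("dose vectors must include 0")
        if v.shape[1:] != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("viability shape does not match dose vectors")
        if not np.isfinite(v).all():
            raise ValueError("viability must be finite")

    @property
    def mean_viability(self) -> np.ndarray:
        return self.viability.mean(axis=0)


@dataclass
class HillFit:
    """Four-parameter Hill fit of a monotherapy curve (% control units)."""

    E0: float
    Einf: float
    EC50: float
    h: float
    rss: float = 0.0
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.EC50 <= 0 or self.h <= 0:
            raise ValueError("EC50 and h must be positive")

    def effect(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, (dose / self.EC50) ** self.h, 0.0)
        return self.Einf + (self.E0 - self.Einf) / (1.0 + ratio)

    def inverse(self, effect: float) -> float:
        """Dose producing ``effect``; inf/0 outside the open range (Einf, E0)."""
        if self.E0 == self.Einf:
            return np.inf
        lo, hi = min(self.E0, self.Einf), max(self.E0, self.Einf)
        if effect >= hi:
            return 0.0
        if effect <= lo:
            return np.inf
        return self.EC50 * ((self.E0 - effect) / (effect - self.Einf)) ** (1.0 / self.h)

    @property
    def inactive(self) -> bool:
        return abs(self.E0 - self.Einf) < 1e-9


def fit_monotherapy(doses, responses, monotone_tol: float = 5.0) -> HillFit:
    """Least-squares Hill fit; needs >= 4 dose points including 0.

    Degenerate (flat) or substantially non-monotone data are fitted anyway
    but flagged in the result.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(doses) < 4 or doses[0] != 0:
        raise ValueError("need at least 4 dose points including dose 0")
    span = responses.max() - responses.min()
    if span < 1e-9:
        return HillFit(
            E0=float(responses[0]), Einf=float(responses[0]) - 1e-12, EC50=float(np.median(doses[doses > 0])),
            h=1.0, rss=0.0, flagged=True, note="flat response; degenerate fit",
        )
    rises = np.diff(responses)
    non_monotone = float(rises[rises > 0].sum()) > monotone_tol

    def model(d, e0, einf, ec50, h):
        return HillFit(E0=e0, Einf=einf, EC50=ec50, h=h).effect(d)

    pos = doses[doses > 0]
    p0 = (float(responses[0]), float(responses.min()), float(np.median(pos)), 1.0)
    bounds = ([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 20.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(
            model, doses, responses, p0=p0, bounds=bounds,
            maxfev=20000, xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
    fit = HillFit(E0=popt[0], Einf=popt[1], EC50=popt[2], h=popt[3])
    fit.rss = float(((fit.effect(doses) - responses) ** 2).sum())
    if non_monotone:
        fit.flagged = True
        fit.note = "non-monotone response beyond tolerance"
    return fit


def loewe_surface(
    fit_a: HillFit, fit_b: HillFit, doses_a, doses_b, rtol: float = 1e-9
) -> np.ndarray:
    """Loewe-additive expected viability at every dose pair.

    Monotherapy rows/columns reproduce the fitted curves.  When one drug is
    inactive (E0 == Einf) its equieffective dose is infinite and the
    expectation collapses to the other drug's monotherapy.  If no root
    exists in the jointly achievable effect range, the expectation is
    clamped to the nearest achievable effect.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    out = np.empty((len(doses_a), len(doses_b)))
    for i, d1 in enumerate(doses_a):
        for j, d2 in enumerate(doses_b):
            if d1 == 0 and d2 == 0:
                out[i, j] = (fit_a.E0 + fit_b.E0) / 2.0
            elif d2 == 0 or fit_b.inactive:
                out[i, j] = fit_a.effect(d1)
            elif d1 == 0 or fit_a.inactive:
                out[i, j] = fit_b.effect(d2)
            else:
                out[i, j] = _loewe_effect(fit_a, fit_b, d1, d2, rtol)
    return out


def _loewe_effect(fit_a: HillFit, fit_b: HillFit, d1: float, d2: float, rtol: float) -> float:
    lo = max(min(fit_a.E0, fit_a.Einf), min(fit_b.E0, fit_b.Einf))
    hi = min(max(fit_a.E0, fit_a.Einf), max(fit_b.E0, fit_b.Einf))
    if hi - lo < 1e-12:
        return lo

    def g(e):
        da, db = fit_a.inverse(e), fit_b.inverse(e)
        term = 0.0
        term += d1 / da if np.isfinite(da) and da > 0 else (np.inf if d1 > 0 and da == 0 else 0.0)
        term += d2 / db if np.isfinite(db) and db > 0 else (np.inf if d2 > 0 and db == 0 else 0.0)
        return term - 1.0

    eps = (hi - lo) * 1e-12
    a, b = lo + eps, hi - eps
    # g(E) runs from about -1 at the strong-effect end (E near lo, D -> inf)
    # to +inf near the no-effect end (E near E0, D -> 0)
    ga, gb = g(a), g(b)
    if ga >= 0:
        return lo  # combination stronger than any shared achievable effect
    if gb <= 0:
        return hi  # combination weaker than the shared effect range
    return float(optimize.brentq(g, a, b, rtol=rtol))


def synergy_matrix(grid: DoseGrid, expected: np.ndarray | None = None) -> pd.DataFrame:
    """Loewe synergy scores: expected minus observed viability.

    Monotherapy fits are taken from the replicate-averaged row/column 0
    unless an ``expected`` surface is supplied.  Returns a tidy frame with
    per-cell mean score and replicate SD; positive scores mean synergy.
    """
    mean_v = grid.mean_viability
    if expected is None:
        fit_a = fit_monotherapy(grid.doses_a, mean_v[:, 0])
        fit_b = fit_monotherapy(grid.doses_b, mean_v[0, :])
        expected = loewe_surface(fit_a, fit_b, grid.doses_a, grid.doses_b)
    scores = expected[None] - grid.viability
    rows = []
    for i, d1 in enumerate(grid.doses_a):
        for j, d2 in enumerate(grid.doses_b):
            rows.append(
                (d1, d2, scores[:, i, j].mean(), scores[:, i, j].std(ddof=0), expected[i, j], mean_v[i, j])
            )
    return pd.DataFrame(
        rows,
        columns=["dose_a", "dose_b", "synergy", "synergy_sd", "expected", "observed"],
    )


def synergy_score_matrix(grid: DoseGrid) -> np.ndarray:
    """Synergy scores as a doses_a x doses_b array (replicate mean)."""
    tidy = synergy_matrix(grid)
    return tidy["synergy"].to_numpy().reshape(len(grid.doses_a), len(grid.doses_b))


def viability_auc(doses, curves: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trapezoidal AUC of survival-fraction curves and group comparison.

    ``curves`` maps line name -> array of shape (n_replicates, n_doses).
    Returns per-replicate AUCs and all pairwise two-sided t-tests on them.
    """
    doses = np.asarray(doses, dtype=float)
    aucs = []
    for line, resp in curves.items():
        resp = np.atleast_2d(np.asarray(resp, dtype=float))
        if resp.shape[1] != len(doses):
            raise ValueError(f"dose vector mismatch for line {line!r}")
        for r, row in enumerate(resp):
            aucs.append((line, r, float(np.trapezoid(row, doses))))
    auc_df = pd.DataFrame(aucs, columns=["line", "replicate", "auc"])
    lines = list(curves)
    comps = []
    for i, a in enumerate(lines):
        for b in lines[i + 1 :]:
            xa = auc_df.loc[auc_df["line"] == a, "auc"]
            xb = auc_df.loc[auc_df["line"] == b, "auc"]
            t, p = stats.ttest_ind(xa, xb)
            comps.append((a, b, xa.mean(), xb.mean(), float(t), float(p)))
    comp_df = pd.DataFrame(
        comps, columns=["line_a", "line_b", "mean_auc_a", "mean_auc_b", "t", "p"]
    )
    return auc_df, comp_df


def drug_candidates(
    de_model: pd.DataFrame,
    de_truth: pd.DataFrame,
    dgi_table: pd.DataFrame,
    n_top: int = 10,
    alpha: float = UPREG_ALPHA,
    min_lfc: float = UPREG_LFC,
) -> pd.DataFrame:
    """Rank shared upregulated genes and join drug-gene interactions.

    Genes significantly upregulated (padj < alpha, effect > min_lfc) in
    both contrasts are ranked by the mean of the two log2 fold changes
    (descending; ties broken lexicographically) and the top ``n_top`` are
    joined against the local drug-gene interaction table (columns
    ``gene, drug, interaction``).  Genes without a drug are kept with NA.
    """
    def upset(df):
        sig = df[(df["padj"] < alpha) & (df["effect"] > min_lfc)]
        return sig.set_index("gene")["effect"]

    up_m, up_t = upset(de_model), upset(de_truth)
    shared = sorted(set(up_m.index) & set(up_t.index))
    if not shared:
        warnings.warn("no shared upregulated genes between contrasts")
        return pd.DataFrame(columns=["gene", "mean_lfc", "rank", "drug", "interaction"])
    mean_lfc = pd.Series({g: (up_m[g] + up_t[g]) / 2.0 for g in shared})
    ranked = mean_lfc.sort_values(ascending=False, kind="mergesort")
    top = ranked.head(n_top).reset_index()
    top.columns = ["gene", "mean_lfc"]
    top["rank"] = np.arange(1, len(top) + 1)
    out = top.merge(dgi_table, on="gene", how="left")
    return out
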