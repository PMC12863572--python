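"""Radial envelopment models (CCR/BCC), slacks, SBM, scale efficiency and
returns-to-scale classification.

Each decision-making unit (DMU) is scored against the piecewise-linear
envelope of all DMUs by linear programming.  The radial input-oriented
program for DMU *o* under constant returns to scale (CRS) is

    min  theta
    s.t. X' lam <= theta x_o,   Y' lam >= y_o,   lam >= 0,

with the convexity constraint ``sum(lam) == 1`` added under variable
returns (VRS).  The classical formulation carries a non-Archimedean
epsilon multiplying total slack in the objective; this implementation
uses the exactly equivalent two-phase procedure — minimize the radial
factor, then maximize total slack holding the radial factor fixed —
which avoids choosing a literal epsilon.

Scores are units-invariant, so inputs and outputs are mean-normalized
before LP assembly for conditioning; slacks are reported back on the
original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from .panel import DMUPanel

__all__ = [
    "EfficiencyResult",
    "BandCounts",
    "RadialDEA",
    "SBM",
    "solve_radial",
    "solve_sbm",
    "extract_slacks",
    "scale_efficiency",
    "classify_rts",
    "efficiency_bands",
]

#: LP feasibility / efficiency tolerance.
LP_TOL = 1e-7
#: tolerance at which theta == 1 and sum(lambda) == 1 are decided.
UNIT_TOL = 1e-6


class DEAError(RuntimeError):
    """An envelopment LP failed (infeasible/unbounded) on validated data."""


@dataclass
class EfficiencyResult:
    """Per-DMU solution of a radial envelopment model.

    Attributes
    ----------
    theta : (n,) radial efficiency in (0, 1] (output orientation is
        reported as the reciprocal of the expansion factor).
    lambdas : (n, n) reference weights; row o holds the weights of the
        peers spanning DMU o's projection.
    input_slacks, output_slacks : phase-2 optimal slacks on the original
        scale (``s- = theta*x - X'lam`` on the input side).
    status : "efficient" | "weakly efficient" | "inefficient" per DMU.
    rts, orientation : model tag.
    """

    theta: np.ndarray
    lambdas: np.ndarray
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    status: np.ndarray
    rts: str
    orientation: str

    @property
    def lambda_sum(self) -> np.ndarray:
        return self.lambdas.sum(axis=1)


def _check_rts(rts: str) -> str:
    rts = rts.lower()
    if rts not in ("crs", "vrs", "nirs"):
        raise ValueError(f"rts must be 'crs', 'vrs' or 'nirs', got {rts!r}")
    return rts


def _lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise DEAError(f"LP failed ({res.status}): {res.message}")
    return res


def _solve_radial_arrays(X: np.ndarray, Y: np.ndarray, rts: str,
                         orientation: str):
    """Two-phase radial DEA on mean-normalized data.

    Returns (theta, lambdas, s_minus, s_plus) with slacks in normalized
    units (caller rescales).
    """
    n, K = X.shape
    M = Y.shape[1]
    theta = np.empty(n)
    lambdas = np.zeros((n, n))
    s_minus = np.zeros((n, K))
    s_plus = np.zeros((n, M))

    conv_eq = rts == "vrs"
    conv_ub = rts == "nirs"

    for o in range(n):
        x_o, y_o = X[o], Y[o]
        # phase 1: variables [factor, lam_1..lam_n]
        if orientation == "input":
            c = np.r_[1.0, np.zeros(n)]
            A_ub = np.block([
                [-x_o[:, None], X.T],          # X'lam <= theta x_o
                [np.zeros((M, 1)), -Y.T],      # Y'lam >= y_o
            ])
            b_ub = np.r_[np.zeros(K), -y_o]
        else:
            c = np.r_[-1.0, np.zeros(n)]
            A_ub = np.block([
                [np.zeros((K, 1)), X.T],       # X'lam <= x_o
                [y_o[:, None], -Y.T],          # Y'lam >= phi y_o
            ])
            b_ub = np.r_[x_o, np.zeros(M)]
        A_eq = b_eq = None
        if conv_eq:
            A_eq = np.r_[0.0, np.ones(n)][None, :]
            b_eq = [1.0]
        if conv_ub:
            A_ub = np.vstack([A_ub, np.r_[0.0, np.ones(n)]])
            b_ub = np.r_[b_ub, 1.0]
        res = _lp(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (n + 1))
        factor = res.x[0]

        # phase 2: max total slack at the fixed radial factor;
        # variables [lam(n), s-(K), s+(M)]
        if orientation == "input":
            target_x, target_y = factor * x_o, y_o
        else:
            target_x, target_y = x_o, factor * y_o
        A2 = np.block([
            [X.T, np.eye(K), np.zeros((K, M))],
            [Y.T, np.zeros((M, K)), -np.eye(M)],
        ])
        b2 = np.r_[target_x, target_y]
        A2_ub = b2_ub = None
        if conv_eq:
            A2 = np.vstack([A2, np.r_[np.ones(n), np.zeros(K + M)]])
            b2 = np.r_[b2, 1.0]
        if conv_ub:
            A2_ub = np.r_[np.ones(n), np.zeros(K + M)][None, :]
            b2_ub = [1.0]
        c2 = np.r_[np.zeros(n), -np.ones(K + M)]
        res2 = _lp(c2, A_ub=A2_ub, b_ub=b2_ub, A_eq=A2, b_eq=b2,
                   bounds=[(0, None)] * (n + K + M))
        lam = res2.x[:n]
        theta[o] = factor if orientation == "input" else 1.0 / factor
        lambdas[o] = lam
        s_minus[o] = res2.x[n:n + K]
        s_plus[o] = res2.x[n + K:]
    return theta, lambdas, s_minus, s_plus


class RadialDEA(BaseEstimator):
    """Radial envelopment DEA estimator (CCR under CRS, BCC under VRS).

    Parameters
    ----------
    rts : {"crs", "vrs", "nirs"}, default "vrs"
        Returns-to-scale assumption of the envelope.
    orientation : {"input", "output"}, default "input"
        Input orientation contracts inputs at given outputs; output
        orientation expands outputs at given inputs (score still
        reported in (0, 1]).
    tol : float
        Tolerance for the efficient/weakly-efficient status calls.

    Attributes (after :meth:`fit`)
    ------------------------------
    efficiency_ : (n,) radial scores in (0, 1].
    lambdas_ : (n, n) reference weights.
    input_slacks_, output_slacks_ : phase-2 slacks, original units.
    status_ : per-DMU efficiency status strings.
    """

    def __init__(self, rts: str = "vrs", orientation: str = "input",
                 tol: float = UNIT_TOL):
        self.rts = rts
        self.orientation = orientation
        self.tol = tol

    def fit(self, X, Y=None):
        if isinstance(X, DMUPanel):
            panel = X
            X, Y = panel.X, panel.Y
        X = np.atleast_2d(np.asarray(X, float))
        Y = np.atleast_2d(np.asarray(Y, float))
        rts = _check_rts(self.rts)
        if self.orientation not in ("input", "output"):
            raise ValueError("orientation must be 'input' or 'output'")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        # mean-normalize for conditioning; theta is units-invariant
        x_scale = X.mean(axis=0)
        y_scale = Y.mean(axis=0)
        x_scale[x_scale == 0] = 1.0
        y_scale[y_scale == 0] = 1.0
        theta, lam, sm, sp = _solve_radial_arrays(
            X / x_scale, Y / y_scale, rts, self.orientation)
        theta = np.clip(theta, LP_TOL, None)
        self.efficiency_ = np.minimum(theta, 1.0)  # clip LP noise above 1
        self.lambdas_ = lam
        self.input_slacks_ = np.maximum(sm * x_scale, 0.0)
        self.output_slacks_ = np.maximum(sp * y_scale, 0.0)
        slack_norm = np.c_[sm, sp].max(axis=1)
        eff = theta >= 1 - self.tol
        self.status_ = np.where(
            eff & (slack_norm < self.tol), "efficient",
            np.where(eff, "weakly efficient", "inefficient"))
        return self

    def result_(self) -> EfficiencyResult:
        return EfficiencyResult(
            theta=self.efficiency_, lambdas=self.lambdas_,
            input_slacks=self.input_slacks_, output_slacks=self.output_slacks_,
            status=self.status_, rts=self.rts.lower(),
            orientation=self.orientation)


def solve_radial(panel: DMUPanel, rts: str = "vrs",
                 orientation: str = "input") -> EfficiencyResult:
    """Solve the radial envelopment model for every DMU of the panel."""
    est = RadialDEA(rts=rts, orientation=orientation).fit(panel)
    return est.result_()


def extract_slacks(result: EfficiencyResult, panel: DMUPanel,
                   total: bool = False) -> np.ndarray:
    """Input slacks of a radial solution, original units.

    With ``total=False`` returns the phase-2 residual slacks
    ``s- = theta*x - X'lam`` (input orientation).  With ``total=True``
    returns the full input excess over the frontier target,
    ``x - X'lam = (1 - theta) x + s-``, i.e. radial reduction plus
    residual slack — the quantity the environmental regressions of a
    three-stage analysis conventionally explain.
    """
    if result.lambdas.shape[1] != panel.n_dmu:
        raise ValueError("result and panel dimensions do not match")
    if not total:
        return result.input_slacks.copy()
    targets = result.lambdas @ panel.X
    return np.maximum(panel.X - targets, 0.0)


def scale_efficiency(crste: np.ndarray, vrste: np.ndarray,
                     tol: float = UNIT_TOL) -> np.ndarray:
    """SE = crste / vrste, the scale component of technical efficiency."""
    crste = np.asarray(crste, float)
    vrste = np.asarray(vrste, float)
    if crste.shape != vrste.shape:
        raise ValueError("score vectors must have equal length")
    if (vrste <= 0).any():
        raise ValueError("vrste must be strictly positive")
    if (crste > vrste + 100 * tol).any():
        bad = np.nonzero(crste > vrste + 100 * tol)[0].tolist()
        raise ValueError(
            f"crste exceeds vrste beyond tolerance at positions {bad}; "
            "CRS scores can never exceed VRS scores on one data set")
    return np.minimum(crste / vrste, 1.0)


def classify_rts(panel: DMUPanel, crs_result: EfficiencyResult,
                 cross_check: bool = False, tol: float = UNIT_TOL):
    """Returns-to-scale label (IRS/CRS/DRS) per DMU from the CRS optimum.

    The sum of the reference weights at the CRS optimum is below 1 for
    DMUs whose efficient peers operate at larger scale (increasing
    returns, IRS), 1 at most-productive scale size (CRS) and above 1
    under decreasing returns (DRS).  Because the optimal reference set
    is often non-unique, the rule is applied to the whole optimal set:
    two secondary LPs bound sum(lambda) at the fixed optimal radial
    factor, and only when the entire range lies below (above) 1 is the
    DMU labelled IRS (DRS).  With ``cross_check=True`` the labels are
    re-derived from the NIRS-frontier comparison (theta_NIRS ==
    theta_CRS -> IRS for scale-inefficient DMUs) and a boolean
    disagreement mask is returned alongside.
    """
    if crs_result.rts != "crs":
        raise ValueError("classify_rts needs a CRS result")
    X, Y = panel.X, panel.Y
    x_scale, y_scale = X.mean(axis=0), Y.mean(axis=0)
    Xn, Yn = X / x_scale, Y / y_scale
    n = panel.n_dmu
    labels = np.empty(n, dtype=object)
    for o in range(n):
        if crs_result.orientation == "input":
            cap_x = crs_result.theta[o] * Xn[o]
            floor_y = Yn[o]
        else:
            cap_x = Xn[o]
            floor_y = Yn[o] / crs_result.theta[o]
        A_ub = np.vstack([Xn.T, -Yn.T])
        b_ub = np.r_[cap_x * (1 + LP_TOL), -floor_y * (1 - LP_TOL)]
        bounds = [(0, None)] * n
        lo = _lp(np.ones(n), A_ub=A_ub, b_ub=b_ub, bounds=bounds).x.sum()
        hi = -_lp(-np.ones(n), A_ub=A_ub, b_ub=b_ub, bounds=bounds).fun
        if hi < 1 - tol:
            labels[o] = "IRS"
        elif lo > 1 + tol:
            labels[o] = "DRS"
        else:
            labels[o] = "CRS"
    labels = labels.astype(str)
    if not cross_check:
        return labels
    vrs = solve_radial(panel, rts="vrs", orientation=crs_result.orientation)
    nirs = solve_radial(panel, rts="nirs", orientation=crs_result.orientation)
    scale_eff = crs_result.theta >= vrs.theta - tol
    nirs_labels = np.where(
        scale_eff, "CRS",
        np.where(np.abs(nirs.theta - crs_result.theta) < tol, "IRS", "DRS"))
    return labels, labels != nirs_labels


class SBM(BaseEstimator):
    """Non-oriented slacks-based measure (SBM) of efficiency.

    Minimizes ``(1 - mean(s-/x_o)) / (1 + mean(s+/y_o))`` over feasible
    envelopment slacks, solved through the Charnes–Cooper linearization.
    The SBM score never exceeds the radial score of the same DMU under
    the same returns assumption, and equals 1 iff the DMU is fully
    efficient (zero slacks).  Requires strictly positive data.

    Attributes: ``efficiency_`` after :meth:`fit`.
    """

    def __init__(self, rts: str = "crs"):
        self.rts = rts

    def fit(self, X, Y=None):
        if isinstance(X, DMUPanel):
            X, Y = X.X, X.Y
        X = np.atleast_2d(np.asarray(X, float))
        Y = np.atleast_2d(np.asarray(Y, float))
        rts = _check_rts(self.rts)
        if (X <= 0).any() or (Y <= 0).any():
            raise ValueError(
                "SBM requires strictly positive inputs and outputs "
                "(slack ratios divide by the evaluated DMU's data)")
        x_scale, y_scale = X.mean(axis=0), Y.mean(axis=0)
        Xn, Yn = X / x_scale, Y / y_scale
        n, K = Xn.shape
        M = Yn.shape[1]
        rho = np.empty(n)
        for o in range(n):
            x_o, y_o = Xn[o], Yn[o]
            # variables [t, Lam(n), S-(K), S+(M)]
            c = np.r_[1.0, np.zeros(n), -1.0 / (K * x_o), np.zeros(M)]
            A_eq = [np.r_[1.0, np.zeros(n + K), 1.0 / (M * y_o)]]
            b_eq = [1.0]
            A_eq.append(np.c_[-x_o[:, None], Xn.T, np.eye(K),
                              np.zeros((K, M))])
            A_eq.append(np.c_[-y_o[:, None], Yn.T, np.zeros((M, K)),
                              -np.eye(M)])
            A_eq = np.vstack([np.atleast_2d(a) for a in A_eq])
            b_eq = np.r_[1.0, np.zeros(K + M)]
            A_ub = b_ub = None
            if rts == "vrs":
                A_eq = np.vstack([A_eq,
                                  np.r_[-1.0, np.ones(n), np.zeros(K + M)]])
                b_eq = np.r_[b_eq, 0.0]
            elif rts == "nirs":
                A_ub = np.r_[-1.0, np.ones(n), np.zeros(K + M)][None, :]
                b_ub = [0.0]
            res = _lp(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * (1 + n + K + M))
            rho[o] = res.fun
        self.efficiency_ = np.clip(rho, LP_TOL, 1.0)
        return self


def solve_sbm(panel: DMUPanel, rts: str = "crs") -> np.ndarray:
    """Slacks-based efficiency for every DMU of the panel."""
    return SBM(rts=rts).fit(panel).efficiency_


@dataclass
class BandCounts:
    """Counts and proportions of scores in the reporting bands
    theta == 1, cut <= theta < 1 and theta < cut."""

    counts: dict[str, int]
    proportions: dict[str, float]
    cut: float

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def efficiency_bands(scores: np.ndarray, cut: float = 0.8,
                     tol: float = 1e-9, as_printed: bool = False) -> BandCounts:
    """Band a score vector into the effective / near-effective / ineffective
    partition used for reporting.

    ``theta == 1`` membership is decided at ``tol`` on the LP score; with
    ``as_printed=True`` scores are first rounded to 2 decimals, matching
    published tables.
    """
    s = np.asarray(scores, float)
    if ((s <= 0) | (s > 1 + 1e-6)).any():
        raise ValueError("scores must lie in (0, 1]")
    if as_printed:
        s = np.round(s, 2)
    full = s >= 1 - tol
    mid = ~full & (s >= cut)
    low = ~full & ~mid
    keys = ["theta=1", f"{cut}<=theta<1", f"theta<{cut}"]
    counts = dict(zip(keys, [int(full.sum()), int(mid.sum()), int(low.sum())]))
    n = len(s)
    props = {k: v / n for k, v in counts.items()}
    return BandCounts(counts=counts, proportions=props, cut=cut)
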