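"""Three-stage DEA orchestration and reporting.

Stage 1 scores every DMU with radial CRS and VRS envelopment on the raw
inputs.  Stage 2 fits one half-normal stochastic frontier per input,
explaining that input's slack by the environmental covariates, and
neutralizes environment and noise out of the inputs.  Stage 3 re-scores
the adjusted panel with the same radial models, so the remaining
inefficiency is managerial.

Reporting follows the conventions of the applied efficiency literature:
technical efficiency TE (CRS score), pure technical efficiency PTE (VRS
score), scale efficiency SE = TE/PTE, returns-to-scale labels, the
three-band partition (theta = 1, cut <= theta < 1, theta < cut), group
means, and Spearman rank consistency across model variants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import BaseEstimator

from .dea import (BandCounts, classify_rts, efficiency_bands,
                  scale_efficiency, solve_radial, extract_slacks)
from .panel import DMUPanel
from .sfa import SFAFit, SlackFrontier, adjust_inputs, AdjustedPanel

__all__ = [
    "PipelineConfig",
    "StageReport",
    "ThreeStageResult",
    "ThreeStageDEA",
    "run_three_stage",
    "rank_consistency",
    "RankConsistency",
    "group_summary",
    "GroupSummary",
    "write_report",
    "read_report",
]

logger = logging.getLogger("tsdea")


@dataclass
class PipelineConfig:
    """Knobs of the three-stage run.

    orientation : radial model orientation for stages 1 and 3.
    sfa_form : "linear" regresses raw slacks; "log" the log1p slacks.
    slack : "total" regresses the full input excess x - X'lam (radial
        reduction plus residual slack); "residual" only the phase-2 slack.
    band_cut : lower edge of the middle reporting band.
    theta_tol : tolerance at which a score counts as exactly 1.
    """

    orientation: str = "input"
    sfa_form: str = "linear"
    slack: str = "total"
    band_cut: float = 0.8
    theta_tol: float = 1e-9

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GroupSummary:
    """Per-group means, band counts and returns-to-scale tallies."""

    means: pd.DataFrame                       # group x (te, pte, se)
    bands: dict[str, dict[str, BandCounts]]   # group -> measure -> bands
    rts: pd.DataFrame                         # group x (IRS, CRS, DRS) counts


@dataclass
class StageReport:
    """Banded efficiency report of one DEA stage."""

    stage: int
    per_dmu: pd.DataFrame          # dmu_id, group, te, pte, se, rts, band
    summary: GroupSummary
    band_cut: float = 0.8

    @property
    def mean_te(self) -> float:
        return float(self.per_dmu["te"].mean())


@dataclass
class ThreeStageResult:
    stage1: StageReport
    sfa_fits: list[SFAFit]
    adjusted: AdjustedPanel
    stage3: StageReport
    config: PipelineConfig = field(default_factory=PipelineConfig)


@dataclass
class RankConsistency:
    """Pairwise Spearman coefficients between model rankings."""

    matrix: pd.DataFrame

    def pair(self, a: str, b: str, ndigits: int | None = 2) -> float:
        v = float(self.matrix.loc[a, b])
        return v if ndigits is None else round(v, ndigits)


def group_summary(scores: pd.DataFrame, groups: np.ndarray,
                  rts_labels: np.ndarray | None = None,
                  cut: float = 0.8, tol: float = 1e-9) -> GroupSummary:
    """Unweighted group means, band counts and RTS tallies.

    ``scores`` must carry the columns to summarize (any subset of
    te/pte/se or named score columns).  Empty groups are impossible by
    construction; groups present in ``groups`` always get a row.
    """
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(scores):
        raise ValueError("groups and scores disagree in length")
    df = scores.copy()
    df["_group"] = groups
    means = df.groupby("_group", sort=True).mean()
    means.index.name = "group"
    bands: dict[str, dict[str, BandCounts]] = {}
    for g, sub in df.groupby("_group", sort=True):
        bands[g] = {c: efficiency_bands(sub[c].to_numpy(), cut=cut, tol=tol)
                    for c in scores.columns}
    if rts_labels is not None:
        rl = pd.DataFrame({"_group": groups, "rts": np.asarray(rts_labels)})
        rts = (rl.value_counts().unstack(fill_value=0)
               .reindex(columns=["IRS", "CRS", "DRS"], fill_value=0))
        rts.index.name = "group"
    else:
        rts = pd.DataFrame(columns=["IRS", "CRS", "DRS"])
    return GroupSummary(means=means, bands=bands, rts=rts)


def _stage_report(panel: DMUPanel, stage: int,
                  config: PipelineConfig) -> tuple[StageReport, np.ndarray]:
    """Radial CRS+VRS scoring of one stage; returns the report and the
    VRS input-slack matrix feeding the SFA stage."""
    crs = solve_radial(panel, "crs", config.orientation)
    vrs = solve_radial(panel, "vrs", config.orientation)
    te, pte = crs.theta, vrs.theta
    se = scale_efficiency(te, pte)
    rts = classify_rts(panel, crs)
    band_obj = efficiency_bands(te, cut=config.band_cut, tol=config.theta_tol)
    keys = list(band_obj.counts)
    band_label = np.where(te >= 1 - config.theta_tol, keys[0],
                          np.where(te >= config.band_cut, keys[1], keys[2]))
    per_dmu = pd.DataFrame({
        "dmu_id": panel.dmu_id, "group": panel.group,
        "te": te, "pte": pte, "se": se, "rts": rts, "band": band_label,
    })
    summary = group_summary(per_dmu[["te", "pte", "se"]], panel.group,
                            rts_labels=rts, cut=config.band_cut,
                            tol=config.theta_tol)
    slacks = extract_slacks(vrs, panel, total=config.slack == "total")
    logger.info("stage %d: n=%d mean TE=%.4f mean PTE=%.4f efficient=%d",
                stage, panel.n_dmu, te.mean(), pte.mean(),
                int((te >= 1 - config.theta_tol).sum()))
    return StageReport(stage=stage, per_dmu=per_dmu, summary=summary,
                       band_cut=config.band_cut), slacks


def _degenerate_fit(name: str, n: int, P: int) -> SFAFit:
    """Stand-in fit for an input whose slack is (numerically) constant —
    nothing to explain, zero adjustment."""
    z = np.zeros(n)
    return SFAFit(input_name=name, form="linear",
                  beta=np.zeros(P + 1), beta_se=np.full(P + 1, np.nan),
                  sigma_sq=0.0, gamma=0.0, loglik=np.nan, ols_loglik=np.nan,
                  lr_stat=0.0, env_component=z, residuals=z,
                  u_hat=z, v_hat=z, boundary_gamma=False, converged=True)


class ThreeStageDEA(BaseEstimator):
    """End-to-end three-stage DEA estimator.

    ``fit(panel)`` runs stage 1 (radial CRS+VRS), stage 2 (one slack
    frontier per input plus input neutralization) and stage 3 (radial
    rerun on adjusted inputs).  Deterministic given the panel and
    parameters.

    Attributes after fit: ``stage1_``, ``sfa_fits_``, ``adjusted_``,
    ``stage3_``, ``result_``.
    """

    def __init__(self, orientation: str = "input", sfa_form: str = "linear",
                 slack: str = "total", band_cut: float = 0.8,
                 theta_tol: float = 1e-9):
        self.orientation = orientation
        self.sfa_form = sfa_form
        self.slack = slack
        self.band_cut = band_cut
        self.theta_tol = theta_tol

    def _config(self) -> PipelineConfig:
        return PipelineConfig(orientation=self.orientation,
                              sfa_form=self.sfa_form, slack=self.slack,
                              band_cut=self.band_cut,
                              theta_tol=self.theta_tol)

    def fit(self, panel: DMUPanel, y=None):
        config = self._config()
        if panel.n_env < 1:
            raise ValueError(
                "three-stage adjustment needs at least one environmental "
                "column; run the radial models directly otherwise")
        if panel.n_dmu <= panel.n_env + 2:
            raise ValueError("too few DMUs for the stage-2 regressions")
        self.stage1_, slacks = _stage_report(panel, 1, config)

        fits: list[SFAFit] = []
        for k in range(panel.n_inputs):
            s_k = slacks[:, k]
            scale = max(1.0, float(np.abs(s_k).max()))
            if s_k.std() < 1e-9 * scale:
                fits.append(_degenerate_fit(panel.input_names[k],
                                            panel.n_dmu, panel.n_env))
                continue
            est = SlackFrontier(form=config.sfa_form,
                                input_name=panel.input_names[k])
            fits.append(est.fit(panel.Z, s_k).result_())
        self.sfa_fits_ = fits
        self.adjusted_ = adjust_inputs(panel, fits)
        self.stage3_, _ = _stage_report(self.adjusted_.to_panel(), 3, config)
        self.result_ = ThreeStageResult(stage1=self.stage1_,
                                        sfa_fits=fits,
                                        adjusted=self.adjusted_,
                                        stage3=self.stage3_, config=config)
        return self


def run_three_stage(panel: DMUPanel,
                    config: PipelineConfig | None = None) -> ThreeStageResult:
    """Run stage 1 -> stage 2 -> stage 3 and return all artifacts."""
    config = config or PipelineConfig()
    est = ThreeStageDEA(**asdict(config)).fit(panel)
    return est.result_


def rank_consistency(score_sets: dict[str, np.ndarray],
                     already_ranked: bool = False) -> RankConsistency:
    """Pairwise Spearman rank correlation between model score vectors.

    Scores are converted to descending ranks (best score = rank 1,
    average ranks on ties); with ``already_ranked=True`` the vectors are
    taken as published integer ranks and used verbatim.
    """
    names = list(score_sets)
    arrs = [np.asarray(v, float) for v in score_sets.values()]
    n = {len(a) for a in arrs}
    if len(n) != 1:
        raise ValueError("all score vectors must have the same length")
    if not already_ranked:
        arrs = [stats.rankdata(-a) for a in arrs]
    m = np.ones((len(arrs), len(arrs)))
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            m[i, j] = m[j, i] = stats.spearmanr(arrs[i], arrs[j]).statistic
    return RankConsistency(matrix=pd.DataFrame(m, index=names, columns=names))


# ---------------------------------------------------------------- report I/O

def _bands_to_dict(b: BandCounts) -> dict:
    return {"counts": b.counts, "proportions": b.proportions, "cut": b.cut}


def write_report(report: StageReport, path: str | Path) -> None:
    """Write a stage report as ``<stem>_dmu.csv`` (per-DMU rows) plus
    ``<stem>_summary.json`` (group means, bands, RTS tallies)."""
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    report.per_dmu.to_csv(stem.with_name(stem.name + "_dmu.csv"), index=False)
    s = report.summary
    payload = {
        "stage": report.stage,
        "band_cut": report.band_cut,
        "group_means": s.means.round(10).to_dict(orient="index"),
        "bands": {g: {m: _bands_to_dict(b) for m, b in per.items()}
                  for g, per in s.bands.items()},
        "rts": s.rts.to_dict(orient="index") if len(s.rts) else {},
    }
    with open(stem.with_name(stem.name + "_summary.json"), "w") as fh:
        json.dump(payload, fh, indent=1)


def read_report(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back what :func:`write_report` wrote."""
    stem = Path(path)
    per_dmu = pd.read_csv(stem.with_name(stem.name + "_dmu.csv"))
    with open(stem.with_name(stem.name + "_summary.json")) as fh:
        summary = json.load(fh)
    return per_dmu, summary


def sfa_summary_table(fits: list[SFAFit],
                      env_names: list[str] | None = None) -> pd.DataFrame:
    """Coefficient/t-value summary of the stage-2 fits, one column pair
    per input, mirroring the usual published layout (rows: constant,
    one per environmental variable, sigma-squared, gamma, LR)."""
    rows: dict[str, list] = {}
    P = len(fits[0].beta) - 1
    names = env_names or [f"z{j + 1}" for j in range(P)]
    index = ["constant", *names, "sigma_sq", "gamma", "LR"]
    for fit in fits:
        tvals = fit.t_values()
        coefs = [*fit.beta, fit.sigma_sq, fit.gamma, fit.lr_stat]
        ts = [*tvals, np.nan, np.nan, np.nan]
        rows[f"{fit.input_name}__coef"] = coefs
        rows[f"{fit.input_name}__t"] = ts
    return pd.DataFrame(rows, index=index)
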