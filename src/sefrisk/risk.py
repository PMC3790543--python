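"""Risk assessment for ecosystem-function vulnerability.

The procedure: estimate phylogenetic signal in the specific effect
function (SEF) and the specific response function (SRF), map each to an
ordinal label, place the system in the four-quadrant scenario matrix
(A: neither patterned ... D: both patterned), measure the SEF-SRF
association both phylogenetically (PGLS) and nonphylogenetically (OLS),
assign an ordinal risk of function loss, and simulate the driver as a
quantile filter on SRF, summarizing the SEF distribution before and
after and the fraction of evolutionary history retained.

Risk logic: function loss is a concern when the species contributing
most (high SEF) are the least tolerant (low SRF), i.e. when SEF and SRF
are negatively correlated; shared phylogenetic patterning (quadrant D)
removes the independent backup of separately evolved providers and
raises the concern to its maximum. Non-negative correlations mean the
function is carried by tolerant species and the specified driver poses
minimal risk to it (whatever it does to evolutionary history).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pgls import PGLSFit, eliminate_predictors, fit_ols, fit_pgls, quadratic_check
from .phylo_core import Phylogeny, PhylogenyError, pd_total
from .signal import DegenerateInputError, DResult, LambdaFit, fit_D, fit_lambda

logger = logging.getLogger(__name__)

__all__ = [
    "SignalCutpoints",
    "CorrelationCutpoints",
    "RunConfig",
    "SignalLabel",
    "CorrelationAssessment",
    "RiskAssessment",
    "FilterResult",
    "SefSummary",
    "AssessmentReport",
    "label_signal",
    "classify_quadrant",
    "assess_correlation",
    "assess_risk",
    "apply_filter",
    "run_assessment",
]

LEVELS = ("none", "weak", "moderate", "strong")
RISK_LEVELS = ("very_low", "low", "high", "maximum")


@dataclass(frozen=True)
class SignalCutpoints:
    """Value -> ordinal-label boundaries for each signal statistic.

    Lambda bands: none < 0.15 <= weak < 0.30 <= moderate < 0.60 <= strong.
    1-D bands: none < 0.20 <= moderate < 0.60 <= strong (no weak band).
    These are the minimal bands consistent with every printed case-study
    label; both are configurable.
    """

    lambda_weak: float = 0.15
    lambda_moderate: float = 0.30
    lambda_strong: float = 0.60
    one_minus_d_moderate: float = 0.20
    one_minus_d_strong: float = 0.60


@dataclass(frozen=True)
class CorrelationCutpoints:
    """r2 boundaries separating negligible / weak / strong association."""

    weak: float = 0.01
    strong: float = 0.30


@dataclass
class RunConfig:
    """Settings for a full assessment run."""

    signal_cutpoints: SignalCutpoints = field(default_factory=SignalCutpoints)
    correlation_cutpoints: CorrelationCutpoints = field(
        default_factory=CorrelationCutpoints
    )
    filter_quantile: float = 0.5
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05            # predictor-elimination threshold
    polytomy_policy: str = "resolve"   # "resolve" | "error" (for binary traits)
    prune: bool = False            # intersect tree/table on label mismatch


@dataclass
class SignalLabel:
    level: str                      # none | weak | moderate | strong
    statistic_kind: str             # "lambda" | "one_minus_d"
    value: float

    @property
    def high_signal(self) -> bool:
        return self.level in ("moderate", "strong")


@dataclass
class CorrelationAssessment:
    phylo_r2: float
    nonphylo_r2: float
    sign: int                       # -1 / 0 / +1, from the OLS slope
    quadratic_p: float
    sign_conflict: bool = False     # PGLS and OLS slopes disagree in sign


@dataclass
class RiskAssessment:
    sef_label: SignalLabel
    srf_label: SignalLabel
    quadrant: str
    correlation: CorrelationAssessment
    risk: str
    maximum_concern: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class SefSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int

    @classmethod
    def of(cls, values: np.ndarray) -> "SefSummary":
        v = np.asarray(values, dtype=float)
        return cls(
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
            min=float(v.min()),
            max=float(v.max()),
            n=int(v.size),
        )


@dataclass
class FilterResult:
    survivors: list[str]
    sef_before: SefSummary
    sef_after: SefSummary
    pd_retained_fraction: float
    quantile_used: float
    n_tied_at_cut: int = 0


@dataclass
class AssessmentReport:
    """Everything one assessment computed, with the settings that drove it."""

    assessment: RiskAssessment
    filter_result: FilterResult
    sef_signal: LambdaFit | DResult
    srf_signal: LambdaFit | DResult
    trait_model: PGLSFit | None
    dropped_predictors: list[str]
    config: RunConfig


# ---------------------------------------------------------------------------
# labeling and classification
# ---------------------------------------------------------------------------


def label_signal(
    value: float,
    kind: str,
    cutpoints: SignalCutpoints | None = None,
) -> SignalLabel:
    """Map a signal statistic (lambda or 1-D) to an ordinal label."""
    cp = cutpoints or SignalCutpoints()
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"signal value must be in [0, 1], got {value}")
    if kind == "lambda":
        if value < cp.lambda_weak:
            level = "none"
        elif value < cp.lambda_moderate:
            level = "weak"
        elif value < cp.lambda_strong:
            level = "moderate"
        else:
            level = "strong"
    elif kind == "one_minus_d":
        if value < cp.one_minus_d_moderate:
            level = "none"
        elif value < cp.one_minus_d_strong:
            level = "moderate"
        else:
            level = "strong"
    else:
        raise ValueError(f"unknown statistic kind: {kind!r}")
    return SignalLabel(level=level, statistic_kind=kind, value=float(value))


def classify_quadrant(sef_label: SignalLabel, srf_label: SignalLabel) -> str:
    """Scenario-matrix cell from the two signal labels.

    none/weak count as low signal, moderate/strong as high:
    (low, low) -> A, (high, low) -> B, (low, high) -> C, (high, high) -> D.
    """
    return {
        (False, False): "A",
        (True, False): "B",
        (False, True): "C",
        (True, True): "D",
    }[(sef_label.high_signal, srf_label.high_signal)]


def assess_correlation(tree: Phylogeny, sef, srf) -> CorrelationAssessment:
    """Dual (phylogenetic and nonphylogenetic) SEF-SRF association.

    phylo_r2 comes from PGLS of SEF on SRF with lambda estimated by ML,
    nonphylo_r2 from OLS; the sign is the OLS slope's, and quadratic_p
    checks the OLS fit for a hidden curved association.
    """
    sef = np.asarray(sef, dtype=float).ravel()
    srf = np.asarray(srf, dtype=float).ravel()
    if sef.size != srf.size or sef.size < 5:
        raise ValueError("need aligned SEF/SRF vectors with n >= 5")
    if np.ptp(sef) == 0 or np.ptp(srf) == 0:
        raise DegenerateInputError("SEF and SRF must both vary across species")
    phylo = fit_pgls(tree, sef, srf, "estimate", predictor_names=["srf"])
    nonphylo = fit_ols(sef, srf, predictor_names=["srf"])
    slope = nonphylo.coef("srf")
    sign = 0 if abs(slope) < 1e-12 else (1 if slope > 0 else -1)
    phylo_slope = phylo.coef("srf")
    phylo_sign = 0 if abs(phylo_slope) < 1e-12 else (1 if phylo_slope > 0 else -1)
    try:
        quad_p = quadratic_check(None, sef, srf, phylogenetic=False)
    except ValueError:
        # binary SRF: x^2 is collinear with x, so no quadratic term exists
        quad_p = float("nan")
    return CorrelationAssessment(
        phylo_r2=float(phylo.r2),
        nonphylo_r2=float(nonphylo.r2),
        sign=sign,
        quadratic_p=float(quad_p),
        sign_conflict=(sign != 0 and phylo_sign != 0 and sign != phylo_sign),
    )


def assess_risk(
    quadrant: str,
    correlation: CorrelationAssessment,
    cutpoints: CorrelationCutpoints | None = None,
) -> tuple[str, bool, list[str]]:
    """Ordinal risk of function loss: (risk, maximum_concern, notes).

    The rule reflects both the strength and the sign of the SEF-SRF
    association. Strength is the larger of the two r2 values. A negative
    association maps strength to very_low / low / high; a high-risk call
    in quadrant D carries the maximum-concern flag (both functions
    patterned: no independent backup). Non-negative associations are
    very_low for the specified driver - the function sits in the tolerant
    species - and are flagged rather than escalated.
    """
    cp = cutpoints or CorrelationCutpoints()
    strength = max(correlation.phylo_r2, correlation.nonphylo_r2)
    notes: list[str] = []
    maximum_concern = False
    if correlation.sign < 0:
        if strength >= cp.strong:
            risk = "high"
            if quadrant == "D":
                maximum_concern = True
                notes.append(
                    "maximum concern: strong negative SEF-SRF correlation with "
                    "phylogenetic patterning in both functions (no independent backup)"
                )
        elif strength >= cp.weak:
            risk = "low"
        else:
            risk = "very_low"
    else:
        risk = "very_low"
        if strength >= cp.strong:
            notes.append(
                "strong positive SEF-SRF correlation: function concentrated "
                "in tolerant species; minimal risk for this driver"
            )
        elif strength >= cp.weak:
            notes.append("weak non-negative SEF-SRF correlation")
    if correlation.sign_conflict:
        notes.append("phylogenetic and nonphylogenetic slopes disagree in sign")
    return risk, maximum_concern, notes


# ---------------------------------------------------------------------------
# driver-filter simulation
# ---------------------------------------------------------------------------


def apply_filter(
    sef,
    srf,
    quantile: float,
    tree: Phylogeny,
    labels: Sequence[str] | None = None,
) -> FilterResult:
    """Simulate the driver: drop the least tolerant fraction of species.

    The cut value is the floor(n*q)-th smallest SRF; species strictly
    above it survive, and when several species tie at the cut value all
    of them survive (the tie count is recorded). Without ties the
    survivor count is ceil(n * (1 - q)). Retained phylogenetic diversity
    is the survivors' branch-length sum over the whole tree's.
    """
    sef = np.asarray(sef, dtype=float).ravel()
    srf = np.asarray(srf, dtype=float).ravel()
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    if sef.size != srf.size:
        raise ValueError("SEF and SRF must be aligned")
    labels = list(labels) if labels is not None else tree.tip_labels
    if len(labels) != sef.size:
        raise ValueError("labels must align with SEF/SRF")

    n = sef.size
    k = int(np.floor(n * quantile))
    n_tied = 0
    if k == 0:
        mask = np.ones(n, dtype=bool)
    else:
        cut = np.sort(srf)[k - 1]
        mask = srf > cut
        tied = srf == cut
        n_tied = int(tied.sum())
        if n_tied > 1:
            logger.info("%d species tied at the SRF cut value; all survive", n_tied)
            mask |= tied
    if not mask.any():
        raise DegenerateInputError("filter removed every species")
    survivors = [lab for lab, m in zip(labels, mask) if m]
    return FilterResult(
        survivors=survivors,
        sef_before=SefSummary.of(sef),
        sef_after=SefSummary.of(sef[mask]),
        pd_retained_fraction=float(
            pd_total(tree, survivors) / pd_total(tree, labels)
        ),
        quantile_used=float(quantile),
        n_tied_at_cut=n_tied if n_tied > 1 else 0,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _unpack_table(table) -> tuple[pd.DataFrame, dict[str, str]]:
    if hasattr(table, "data") and hasattr(table, "roles"):
        return table.data, dict(table.roles)
    if hasattr(table, "table") and hasattr(table, "roles"):
        return table.table, dict(table.roles)
    raise TypeError("table must expose a species-indexed frame and a role map")


def _is_binary(values: np.ndarray) -> bool:
    return bool(np.all(np.isin(values, (0.0, 1.0))))


def _signal_for(
    tree: Phylogeny, values: np.ndarray, config: RunConfig, seed: int
) -> tuple[LambdaFit | DResult, SignalLabel]:
    if _is_binary(values):
        work_tree = tree
        if not tree.is_binary:
            if config.polytomy_policy != "resolve":
                raise PhylogenyError(
                    "binary-trait signal needs a binary tree; set "
                    "polytomy_policy='resolve' to break polytomies with "
                    "zero-length edges"
                )
            work_tree = tree.resolve_polytomies()
        fit = fit_D(work_tree, values, n_perm=config.n_perm, seed=seed)
        value = float(np.clip(fit.one_minus_d, 0.0, 1.0))
        return fit, label_signal(value, "one_minus_d", config.signal_cutpoints)
    fit = fit_lambda(tree, values)
    return fit, label_signal(fit.lambda_hat, "lambda", config.signal_cutpoints)


def run_assessment(
    tree: Phylogeny,
    table,
    config: RunConfig | None = None,
) -> AssessmentReport:
    """Full pipeline: signal -> labels -> quadrant -> correlation -> risk -> filter.

    ``table`` is any object carrying a species-indexed numeric frame and a
    column -> role map with exactly one ``sef`` and one ``srf`` (or
    ``srf_proxy``) role; proxy transforms are applied at load time.
    Effect-trait columns, if present, additionally drive a PGLS model of
    the SEF with single-step backward elimination.
    """
    config = config or RunConfig()
    data, roles = _unpack_table(table)

    sef_cols = [c for c, r in roles.items() if r == "sef"]
    srf_cols = [c for c, r in roles.items() if r in ("srf", "srf_proxy")]
    if len(sef_cols) != 1 or len(srf_cols) != 1:
        raise ValueError(
            "table must declare exactly one sef column and one srf/srf_proxy "
            f"column (got sef={sef_cols}, srf={srf_cols})"
        )
    trait_cols = [c for c, r in roles.items() if r == "effect_trait"]

    table_species = [str(s).strip() for s in data.index]
    tree_species = set(tree.tip_labels)
    if set(table_species) != tree_species:
        common = sorted(set(table_species) & tree_species)
        if not config.prune:
            only_tree = sorted(tree_species - set(table_species))
            only_table = sorted(set(table_species) - tree_species)
            raise PhylogenyError(
                "tree and table species differ (use prune to intersect); "
                f"tree-only={only_tree[:10]}, table-only={only_table[:10]}"
            )
        if len(common) < 4:
            raise PhylogenyError("fewer than 4 species shared by tree and table")
        tree = tree.prune_to(common)
        data = data.loc[[s for s in table_species if s in tree_species]]
    data = data.loc[tree.tip_labels]

    rng = np.random.default_rng(config.seed)
    sef_seed = int(rng.integers(2**31))
    srf_seed = int(rng.integers(2**31))

    sef = data[sef_cols[0]].to_numpy(dtype=float)
    srf = data[srf_cols[0]].to_numpy(dtype=float)

    sef_fit, sef_label = _signal_for(tree, sef, config, sef_seed)
    srf_fit, srf_label = _signal_for(tree, srf, config, srf_seed)
    quadrant = classify_quadrant(sef_label, srf_label)
    correlation = assess_correlation(tree, sef, srf)
    risk, maximum_concern, notes = assess_risk(
        quadrant, correlation, config.correlation_cutpoints
    )
    assessment = RiskAssessment(
        sef_label=sef_label,
        srf_label=srf_label,
        quadrant=quadrant,
        correlation=correlation,
        risk=risk,
        maximum_concern=maximum_concern,
        notes=notes,
    )
    filter_result = apply_filter(
        sef, srf, config.filter_quantile, tree, tree.tip_labels
    )

    trait_model = None
    dropped: list[str] = []
    if trait_cols:
        X = data[trait_cols].to_numpy(dtype=float)
        trait_model, dropped = eliminate_predictors(
            tree, sef, X, trait_cols, alpha=config.alpha
        )

    return AssessmentReport(
        assessment=assessment,
        filter_result=filter_result,
        sef_signal=sef_fit,
        srf_signal=srf_fit,
        trait_model=trait_model,
        dropped_predictors=dropped,
        config=config,
    )
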