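"""Statistical layer: Spearman correlations with interpretation bands,
nested-random-effect linear mixed models with likelihood-ratio tests, and
treatment-delta reporting.

Correlation magnitudes are banded following the Schober guidelines:
negligible |r| < 0.10, weak [0.10, 0.40), moderate [0.40, 0.70), strong
[0.70, 0.90), very strong >= 0.90.  Mixed models are random-intercept
models fit by maximum likelihood with the nesting appropriate to the
modality (dog; side within dog; segment within side); the treatment effect
is tested with a likelihood-ratio test against the model without treatment,
referenced to chi-square(1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import InvalidInputError, RegionalSummary

SCHOBER_BANDS = (
    (0.10, "negligible"),
    (0.40, "weak"),
    (0.70, "moderate"),
    (0.90, "strong"),
    (np.inf, "very strong"),
)


def schober_band(r: float) -> str:
    """Interpretation band for a correlation coefficient (applied to |r|;
    boundary values go to the higher band)."""
    a = abs(r)
    for upper, name in SCHOBER_BANDS:
        if a < upper:
            return name
    return "very strong"


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    p_corrected: float
    band: str
    n: int
    sign: int
    flags: tuple[str, ...] = ()


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (tie-free)."""
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c @ rx_c) * (ry_c**2).sum(axis=1))
    rhos = ry_c @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(r_obs) - 1e-12))


def spearman_correlate(x, y, m: int = 1, pair: tuple[str, str] = ("x", "y"),
                       ) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with Bonferroni correction.

    ``m`` is the number of tests in the batch; the corrected p is
    min(1, m * p).  p-values use the t approximation for n >= 10 and exact
    permutation enumeration below that (when tie-free).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise InvalidInputError("need paired samples with n >= 5")
    flags: list[str] = []
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(pair=pair, r=float("nan"), p=float("nan"),
                                 p_corrected=float("nan"), band="undefined",
                                 n=x.size, sign=0, flags=("constant-input",))
    r, p = sps.spearmanr(x, y)
    ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    if x.size < 10 and not ties:
        p = _exact_spearman_p(x, y, r)
        flags.append("exact-permutation-p")
    return CorrelationResult(pair=pair, r=float(r), p=float(p),
                             p_corrected=min(1.0, m * float(p)),
                             band=schober_band(r), n=x.size,
                             sign=int(np.sign(r)), flags=tuple(flags))


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    outcome: str
    estimate: float
    se: float
    lrt: float
    p: float
    variance_components: dict[str, float]
    structure: tuple[str, ...]
    converged: bool = True
    flags: tuple[str, ...] = ()

    def summary(self) -> str:
        vc = ", ".join(f"{k}={v:.4g}" for k, v in self.variance_components.items())
        return (f"{self.outcome}: treatment effect = {self.estimate:.4f} "
                f"(SE {self.se:.4f}), LRT = {self.lrt:.3f}, p = {self.p:.3g}\n"
                f"  random effects: {vc}")


def _fit_lmm(records: pd.DataFrame, outcome: str, structure: tuple[str, ...],
             with_treatment: bool):
    """ML fit of a random-intercept model with the nesting chain given by
    ``structure`` (first element = grouping factor, the rest variance
    components nested below it)."""
    import statsmodels.formula.api as smf

    df = records.copy()
    df["_y"] = df[outcome] if outcome in df else df["value"]
    formula = "_y ~ C(treatment)" if with_treatment else "_y ~ 1"
    groups = df[structure[0]].astype(str)
    vc = {}
    prev = structure[0]
    for level in structure[1:]:
        df[f"_{level}_key"] = df[prev].astype(str) + ":" + df[level].astype(str) \
            if prev != structure[0] else df[level].astype(str)
        vc[level] = f"0 + C(_{level}_key)"
        prev = level
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=groups, vc_formula=vc or None)
        last_exc: Exception | None = None
        for method in (None, "powell", "cg"):
            try:
                return model.fit(reml=False, **({"method": method} if method else {}))
            except Exception as exc:  # singular hessian at a boundary, etc.
                last_exc = exc
        raise last_exc


class TreatmentEffectModel:
    """Treatment fixed effect on one outcome with nested random intercepts.

    ``structure`` is the nesting chain, e.g. ("dog",) for CEUS,
    ("dog", "side") for DCE, ("dog", "side", "segment") for ASL/BOLD
    per-segment records.  Levels absent from the records are dropped.
    """

    def __init__(self, records: pd.DataFrame, outcome: str = "value",
                 structure: tuple[str, ...] = ("dog", "side")):
        if records["treatment"].nunique() < 2:
            raise InvalidInputError("both treatments must be present")
        if records[structure[0]].nunique() < 2:
            raise InvalidInputError("need at least 2 subjects")
        self.records = records
        self.outcome = outcome
        self.structure = tuple(s for s in structure if s in records.columns
                               and records[s].nunique() > 1 or s == structure[0])

    def fit(self) -> EffectResult:
        structure = self.structure
        flags: list[str] = []
        full = null = None
        while True:
            try:
                cand_full = _fit_lmm(self.records, self.outcome, structure, True)
                cand_null = _fit_lmm(self.records, self.outcome, structure, False)
                ok = np.all(np.isfinite(cand_full.bse_fe))
                if ok:
                    full, null = cand_full, cand_null
                    if not cand_full.converged:
                        # boundary (zero-variance) solutions are retained, flagged
                        flags.append(f"non-converged at {structure}")
                    break
            except Exception:
                ok = False
            if len(structure) == 1:
                break
            flags.append(f"singular-fit: dropped '{structure[-1]}' nesting")
            structure = structure[:-1]
        if full is None:
            raise InvalidInputError("mixed model failed to converge")

        # treatment coefficient: the single non-intercept fixed effect
        names = [n for n in full.fe_params.index if n != "Intercept"]
        est = float(full.fe_params[names[0]])
        se = float(full.bse_fe[names[0]])
        lrt = max(0.0, 2.0 * (full.llf - null.llf))
        p = float(sps.chi2.sf(lrt, df=1))
        vcomp = {"residual": float(full.scale)}
        vcomp[structure[0]] = float(np.atleast_2d(full.cov_re)[0, 0]) if full.cov_re.size else 0.0
        for name, val in zip(full.model.exog_vc.names, np.atleast_1d(full.vcomp)):
            vcomp[name] = float(val)
        return EffectResult(outcome=self.outcome, estimate=est, se=se, lrt=lrt,
                            p=min(max(p, np.nextafter(0, 1)), 1.0),
                            variance_components=vcomp, structure=structure,
                            converged=bool(full.converged),
                            flags=tuple(flags))


def lmm_treatment_effect(records: pd.DataFrame, outcome: str = "value",
                         structure: tuple[str, ...] = ("dog", "side")
                         ) -> EffectResult:
    """Fit the treatment effect LMM and LRT; see :class:`TreatmentEffectModel`."""
    return TreatmentEffectModel(records, outcome=outcome, structure=structure).fit()


# ---------------------------------------------------------------------------
# treatment deltas
# ---------------------------------------------------------------------------

def treatment_delta(summary_treated: RegionalSummary,
                    summary_control: RegionalSummary) -> pd.DataFrame:
    """Per-region and per-aggregate differences, treated minus control.

    Returns a table with columns region, treated_mean, treated_sd,
    control_mean, control_sd, delta (units of the underlying map).
    """
    if summary_treated.scheme != summary_control.scheme:
        raise InvalidInputError("summaries use different partition schemes")
    rows = []
    for rid, (m_t, s_t, _) in summary_treated.per_region.items():
        if rid not in summary_control.per_region:
            raise InvalidInputError(f"region {rid} missing from control summary")
        m_c, s_c, _ = summary_control.per_region[rid]
        rows.append((str(rid), m_t, s_t, m_c, s_c, m_t - m_c))
    for name, (m_t, s_t, _) in summary_treated.aggregates.items():
        m_c, s_c, _ = summary_control.aggregates[name]
        rows.append((name, m_t, s_t, m_c, s_c, m_t - m_c))
    return pd.DataFrame(rows, columns=["region", "treated_mean", "treated_sd",
                                       "control_mean", "control_sd", "delta"])


def summary_from_means(scheme: str, kind: str,
                       region_means: dict[int | str, float | tuple[float, float]]
                       ) -> RegionalSummary:
    """Build a RegionalSummary from printed per-region means (and optional
    SDs), e.g. from a published regional table, for delta reporting."""
    out = RegionalSummary(scheme=scheme, kind=kind)
    for key, val in region_means.items():
        mean, sd = (val if isinstance(val, (tuple, list)) else (val, float("nan")))
        entry = (float(mean), float(sd), 0)
        if isinstance(key, str):
            out.aggregates[key] = entry
        else:
            out.per_region[int(key)] = entry
    return out
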