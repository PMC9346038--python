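"""Fixed Effects Likelihood (FEL) estimation of per-codon selection.

For each codon column, the synonymous rate alpha and non-synonymous rate
beta scale the synonymous and non-synonymous components of the globally
fitted MG94xREV generator on every branch, with branch lengths, REV
exchangeabilities and codon frequencies held at the alignment-wide
maximum-likelihood fit (two-stage FEL). The site's dN/dS is
omega = beta/alpha, tested against the neutral null alpha = beta by a
one-degree-of-freedom likelihood ratio with the asymptotic chi-square
reference, and bracketed by a 95% profile-likelihood interval over the
omega ray (the scale of the two rates re-optimized at each omega).

Columns that are invariant at a single-codon amino acid (e.g. the
strictly aligned initiator methionine, internal Met/Trp) have
alpha = beta = 0 and an undefined omega (0/0); columns with amino-acid
variation but no synonymous variation drive alpha to 0 and omega to
infinity. Both statuses are tracked explicitly and excluded from every
downstream aggregate fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .code import UNIVERSAL, GeneticCode
from .fitting import GlobalFit
from .io import ReferenceColumnMap, map_alignment_to_reference
from .likelihood import TreeArrays, alignment_loglik
from .mg94 import Spectral, mg94_components, spectral_decompose

RATE_FLOOR = 1e-8  # optimizer boundary noise below this reports as 0
OMEGA_CAP = 1e4  # profile upper-bound search cap; beyond -> +inf flag
_SCALE_LO, _SCALE_HI = 1e-9, 100.0

STATUS_DEFINED = "defined"
STATUS_UNDEFINED = "undefined_0_over_0"
STATUS_INFINITE = "infinite_beta_over_0"

CLASS_PURIFYING = "purifying"
CLASS_NEUTRAL = "neutral"
CLASS_DIVERSIFYING = "diversifying"
CLASS_UNDEFINED = "undefined"


@dataclass
class SiteResult:
    """Per-codon FEL estimates, test, interval and selection call."""

    site: int
    alpha: float
    beta: float
    omega: float  # nan when 0/0, inf when beta/0
    omega_status: str
    ci_lower: float
    ci_upper: float
    lrt: float
    p_value: float
    cls: str

    @property
    def defined(self) -> bool:
        return self.omega_status == STATUS_DEFINED


@dataclass
class FELContext:
    """Everything a site fit needs from the global stage.

    ``q_syn``/``q_non`` are the synonymous and non-synonymous components
    of the fitted generator, jointly normalized so that alpha = beta = 1
    reproduces the neutral (omega = 1) matrix scaled to one expected
    substitution per codon site per unit branch length.
    """

    tree: TreeArrays
    q_syn: np.ndarray
    q_non: np.ndarray
    freqs: np.ndarray
    states: np.ndarray
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL)
    _spec_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_global_fit(cls, fit: GlobalFit) -> "FELContext":
        if fit.states is None or fit.tree_arrays is None:
            raise ValueError("global fit lacks cached alignment state")
        p = fit.params
        a_syn, a_non = mg94_components(p.rev_rates, p.position_freqs, p.code)
        pi = p.codon_freqs
        z1 = float(pi @ (a_syn + a_non).sum(axis=1))
        return cls(fit.tree_arrays, a_syn / z1, a_non / z1, pi, fit.states, p.code)

    # -- spectral factorizations, cached per omega ----------------------
    def _generator(self, omega: float) -> np.ndarray:
        if np.isinf(omega):
            q = self.q_non.copy()
        else:
            q = self.q_syn + omega * self.q_non
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def spectral(self, omega: float) -> Spectral:
        key = float(omega)
        spec = self._spec_cache.get(key)
        if spec is None:
            spec = spectral_decompose(self._generator(omega), self.freqs)
            if len(self._spec_cache) > 64:
                self._spec_cache.clear()
            self._spec_cache[key] = spec
        return spec

    # -- likelihood over a column subset --------------------------------
    def loglik(self, cols: np.ndarray, omega: float, scale: float) -> float:
        total, _ = alignment_loglik(
            self.tree, self.states[:, cols], self.spectral(omega), self.freqs, rate=scale
        )
        return total

    def profile(self, cols: np.ndarray, omega: float) -> tuple[float, float]:
        """Max log-likelihood over the rate scale at fixed omega; (logL, scale)."""
        spec = self.spectral(omega)
        sub = self.states[:, cols]

        def neg(log_s: float) -> float:
            t, _ = alignment_loglik(self.tree, sub, spec, self.freqs, rate=np.exp(log_s))
            # keep the objective finite at extreme scales so the bounded
            # optimizer's interpolation never produces inf - inf
            return -t if np.isfinite(t) else 1e300

        r = minimize_scalar(
            neg,
            bounds=(np.log(_SCALE_LO), np.log(_SCALE_HI)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        return -float(r.fun), float(np.exp(r.x))


@dataclass
class _RayFit:
    loglik: float
    alpha: float
    beta: float
    omega_ray: float  # the ray maximized over (inf for the alpha=0 boundary)


def _fit_omega_ray(ctx: FELContext, cols: np.ndarray) -> _RayFit:
    """Maximize over (omega, scale): interior ray plus both boundaries."""

    def neg(logw: float) -> float:
        return -ctx.profile(cols, float(np.exp(logw)))[0]

    r = minimize_scalar(
        neg,
        bounds=(np.log(1e-6), np.log(OMEGA_CAP)),
        method="bounded",
        options={"xatol": 1e-5},
    )
    w_int = float(np.exp(r.x))
    ll_int, s_int = ctx.profile(cols, w_int)

    ll0, s0 = ctx.profile(cols, 0.0)
    llinf, sinf = ctx.profile(cols, np.inf)

    best = _RayFit(ll_int, s_int, s_int * w_int, w_int)
    if ll0 >= best.loglik:
        best = _RayFit(ll0, s0, 0.0, 0.0)
    if llinf > best.loglik + 1e-9:
        best = _RayFit(llinf, 0.0, sinf, np.inf)
    return best


def fel_fit_site(
    fit_or_ctx: GlobalFit | FELContext,
    site: int,
    ref_map: ReferenceColumnMap | None = None,
    *,
    p_threshold: float = 0.1,
    ci_level: float = 0.95,
    compute_ci: bool = True,
) -> SiteResult:
    """FEL estimates and test for one reference codon site (1-based)."""
    ctx = fit_or_ctx if isinstance(fit_or_ctx, FELContext) else FELContext.from_global_fit(fit_or_ctx)
    if ref_map is not None:
        inv = ref_map.ref_to_column
        if site not in inv:
            raise ValueError(f"reference codon {site} is not mapped in this alignment")
        col = inv[site]
    else:
        if not (1 <= site <= ctx.states.shape[1]):
            raise ValueError(f"codon index {site} out of range")
        col = site - 1
    return _fit_column(ctx, col, site, p_threshold, ci_level, compute_ci)


def _fit_column(
    ctx: FELContext,
    col: int,
    site_label: int,
    p_threshold: float,
    ci_level: float,
    compute_ci: bool,
) -> SiteResult:
    cols = np.array([col])

    observed = ctx.states[:, col]
    observed = observed[observed >= 0]
    if observed.size == 0 or (observed == observed[0]).all():
        # Structurally invariant column: total rate 0 is the exact MLE, so
        # alpha = beta = 0 without consulting the bounded optimizer.
        res = SiteResult(
            site_label, 0.0, 0.0, float("nan"), STATUS_UNDEFINED,
            0.0, float("inf"), 0.0, 1.0, "",
        )
        res.cls = classify_site(res, p_threshold)
        return res

    alt = _fit_omega_ray(ctx, cols)
    ll_null, _ = ctx.profile(cols, 1.0)  # alpha = beta, total rate free
    ll_alt = max(alt.loglik, ll_null)

    alpha = 0.0 if alt.alpha < RATE_FLOOR else alt.alpha
    beta = 0.0 if alt.beta < RATE_FLOOR else alt.beta
    if alpha == 0.0 and beta == 0.0:
        status, omega = STATUS_UNDEFINED, float("nan")
    elif alpha == 0.0:
        status, omega = STATUS_INFINITE, float("inf")
    else:
        status, omega = STATUS_DEFINED, beta / alpha

    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(chi2.sf(lrt, df=1)) if lrt > 0 else 1.0

    if status == STATUS_UNDEFINED or not compute_ci:
        lo, hi = 0.0, float("inf")
    else:
        lo, hi = profile_confidence_interval(ctx, cols, ll_alt, omega, level=ci_level)

    res = SiteResult(site_label, alpha, beta, omega, status, lo, hi, lrt, p, "")
    res.cls = classify_site(res, p_threshold)
    return res


def profile_confidence_interval(
    ctx: FELContext,
    cols: np.ndarray,
    ll_max: float,
    omega_hat: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood interval for omega over a column set.

    Bounds are the extreme omega values whose profile log-likelihood
    (scale re-optimized) stays within chi2_1(level)/2 of the maximum;
    the lower bound floors at 0 and an upper search escaping the cap of
    10^4 is flagged +inf.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    cut = ll_max - chi2.ppf(level, df=1) / 2.0
    slack = 1e-7

    def above(w: float) -> bool:
        return ctx.profile(cols, w)[0] >= cut - slack

    # Lower bound
    if np.isinf(omega_hat):
        anchor = OMEGA_CAP
    elif omega_hat <= 0:
        anchor = 0.0
    else:
        anchor = omega_hat
    if anchor == 0.0 or above(0.0):
        lo = 0.0
    else:
        hi_b, lo_b = anchor, anchor / 8.0
        while lo_b > 1e-9 and above(lo_b):
            hi_b, lo_b = lo_b, lo_b / 8.0
        if lo_b <= 1e-9 and above(lo_b):
            lo = 0.0
        else:
            lo = _bisect_log(above, lo_b, hi_b, want_above_high=True)

    # Upper bound
    if np.isinf(omega_hat):
        hi = float("inf")
    else:
        start = max(omega_hat, 1e-3)
        lo_b, hi_b = start, start * 4.0
        while hi_b <= OMEGA_CAP and above(hi_b):
            lo_b, hi_b = hi_b, hi_b * 4.0
        if hi_b > OMEGA_CAP:
            hi = float("inf") if above(OMEGA_CAP) else _bisect_log(
                above, lo_b, OMEGA_CAP, want_above_high=False
            )
        else:
            hi = _bisect_log(above, lo_b, hi_b, want_above_high=False)

    if np.isfinite(omega_hat):
        lo = min(lo, omega_hat)
        hi = max(hi, omega_hat)
    return lo, hi


def _bisect_log(above, a: float, b: float, want_above_high: bool, tol: float = 5e-3) -> float:
    """Bisect in log10 space for the crossing of the profile cut.

    ``want_above_high`` says whether the accepted region lies at the high
    end of [a, b] (lower-bound search) or the low end (upper-bound).
    """
    la, lb = np.log10(max(a, 1e-12)), np.log10(b)
    while lb - la > tol:
        mid = 0.5 * (la + lb)
        ok = above(10**mid)
        if ok == want_above_high:
            lb = mid
        else:
            la = mid
    return float(10 ** (0.5 * (la + lb)))


def classify_site(result: SiteResult, p_threshold: float = 0.1) -> str:
    """Selection call: purifying / diversifying need omega on the right
    side of 1 AND LRT p <= threshold; otherwise neutral; 0/0 sites are
    undefined."""
    if result.omega_status == STATUS_UNDEFINED:
        return CLASS_UNDEFINED
    if result.p_value <= p_threshold:
        if result.omega < 1.0:
            return CLASS_PURIFYING
        if result.omega > 1.0:
            return CLASS_DIVERSIFYING
    return CLASS_NEUTRAL


@dataclass
class FELScan:
    """All per-site results of a scan, in reference order, plus counts."""

    results: list[SiteResult]
    counts: dict[str, int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [r.site for r in self.results],
                "alpha": [r.alpha for r in self.results],
                "beta": [r.beta for r in self.results],
                "omega": [r.omega for r in self.results],
                "omega_status": [r.omega_status for r in self.results],
                "ci_lower": [r.ci_lower for r in self.results],
                "ci_upper": [r.ci_upper for r in self.results],
                "lrt": [r.lrt for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "class": [r.cls for r in self.results],
            }
        )

    def undefined_sites(self) -> list[int]:
        """Sites with omega_status undefined_0_over_0; these (and only
        these) are dropped from downstream aggregate fits. Infinite-omega
        sites carry real non-synonymous signal and stay in aggregates."""
        return [r.site for r in self.results if r.omega_status == STATUS_UNDEFINED]


def fel_scan(
    fit: GlobalFit,
    ref_map: ReferenceColumnMap | None = None,
    *,
    p_threshold: float = 0.1,
    ci_level: float = 0.95,
    compute_ci: bool = True,
) -> FELScan:
    """FEL over every mapped reference codon, in reference order."""
    ctx = FELContext.from_global_fit(fit)
    if ref_map is None and fit.alignment is not None and fit.alignment.reference:
        ref_map = map_alignment_to_reference(fit.alignment)
    if ref_map is None:
        pairs = [(c, c + 1) for c in range(ctx.states.shape[1])]
    else:
        pairs = [(c, ref_map.column_to_ref[c]) for c in ref_map.mapped_columns()]
    results = [
        _fit_column(ctx, col, ref, p_threshold, ci_level, compute_ci) for col, ref in pairs
    ]
    counts: dict[str, int] = {
        CLASS_PURIFYING: 0,
        CLASS_NEUTRAL: 0,
        CLASS_DIVERSIFYING: 0,
        CLASS_UNDEFINED: 0,
    }
    for r in results:
        counts[r.cls] += 1
    return FELScan(results, counts)
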