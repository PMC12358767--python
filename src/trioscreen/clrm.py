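"""Conditional logistic regression for 1:1 matched pairs with a 7-term
dose-interaction design.

The screening model for a drug triplet codes each drug's 30-day average
daily dose as 0 (none), 1 (low) or 2 (high) and models the log-odds of
being the case within a matched pair as

    alpha + b1*x1 + b2*x2 + b3*x3 + b4*x1*x2 + b5*x1*x3 + b6*x2*x3
          + b7*x1*x2*x3

where ``alpha`` is the pair-specific nuisance intercept.  Conditioning on
one case per pair eliminates ``alpha`` exactly: the conditional likelihood
of a pair with case design row ``u`` and control design row ``v`` is
``exp(b.u) / (exp(b.u) + exp(b.v))``, i.e. a logistic likelihood on the
within-pair difference ``u - v`` with outcome fixed at 1 and no intercept.
Only discordant pairs (``u != v``) inform the fit; concordant pairs each
contribute a constant ``log 1/2``.

Estimation is Newton-Raphson with step-halving started at ``beta = 0``.
The conditional log-likelihood is concave, so the deterministic optimizer
gives bit-stable results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit
from scipy.stats import norm

from .errors import DataError, DegenerateContrastError, FitError, RankDeficiencyError

#: Names of the seven regressors, in design-row order.
TERM_NAMES = ("x1", "x2", "x3", "x1x2", "x1x3", "x2x3", "x1x2x3")

#: |beta| beyond which a non-vanishing gradient is treated as separation.
SEPARATION_BOUND = 15.0

GRAD_TOL = 1e-8
MAX_ITER = 100


def design_row(x1: int, x2: int, x3: int) -> np.ndarray:
    """Return the 7-vector (x1, x2, x3, x1x2, x1x3, x2x3, x1x2x3).

    Each dose code must be 0, 1 or 2.
    """
    codes = (x1, x2, x3)
    if any(x not in (0, 1, 2) for x in codes):
        raise DataError(f"dose codes must be in {{0,1,2}}, got {codes}")
    return np.array(
        [x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1 * x2 * x3], dtype=float
    )


def design_matrix(codes: np.ndarray) -> np.ndarray:
    """Vectorised :func:`design_row` for an (n, 3) array of dose codes."""
    codes = np.asarray(codes, dtype=float)
    if codes.ndim != 2 or codes.shape[1] != 3:
        raise DataError("codes must have shape (n, 3)")
    if not np.isin(codes, (0.0, 1.0, 2.0)).all():
        raise DataError("dose codes must be in {0,1,2}")
    x1, x2, x3 = codes[:, 0], codes[:, 1], codes[:, 2]
    return np.column_stack(
        [x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1 * x2 * x3]
    )


@dataclass
class TripletDesign:
    """Per-pair case/control design rows for one drug triplet.

    ``case_rows`` and ``control_rows`` are (n_pairs, 7) arrays whose rows
    must be internally consistent (interaction entries equal the products
    of the first three).
    """

    triplet: tuple[str, str, str]
    case_rows: np.ndarray
    control_rows: np.ndarray

    def __post_init__(self) -> None:
        self.case_rows = np.asarray(self.case_rows, dtype=float)
        self.control_rows = np.asarray(self.control_rows, dtype=float)
        if self.case_rows.shape != self.control_rows.shape:
            raise DataError("case and control row blocks must have equal shape")
        if self.case_rows.ndim != 2 or self.case_rows.shape[1] != 7:
            raise DataError("design rows must have 7 columns")
        for rows in (self.case_rows, self.control_rows):
            _verify_products(rows)

    @classmethod
    def from_codes(
        cls,
        triplet: tuple[str, str, str],
        case_codes: np.ndarray,
        control_codes: np.ndarray,
    ) -> "TripletDesign":
        """Build the design from (n, 3) dose-code arrays."""
        return cls(tuple(triplet), design_matrix(case_codes), design_matrix(control_codes))

    @property
    def n_pairs(self) -> int:
        return self.case_rows.shape[0]

    def differences(self) -> np.ndarray:
        """Within-pair regressor differences (case minus control)."""
        return self.case_rows - self.control_rows


def _verify_products(rows: np.ndarray) -> None:
    x = rows[:, :3]
    if not np.isin(x, (0.0, 1.0, 2.0)).all():
        raise DataError("dose codes must be in {0,1,2}")
    expected = np.column_stack(
        [x[:, 0] * x[:, 1], x[:, 0] * x[:, 2], x[:, 1] * x[:, 2], x.prod(axis=1)]
    )
    if not np.array_equal(rows[:, 3:], expected):
        raise DataError("interaction columns inconsistent with dose codes")


@dataclass
class ConditionalFit:
    """Result of maximising a 1:1 conditional logistic likelihood."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separation_flag: bool
    n_pairs: int
    n_discordant: int
    n_iter: int


@dataclass
class TripletFit(ConditionalFit):
    """A :class:`ConditionalFit` for the full 7-term triplet design."""

    triplet: tuple[str, str, str] = ("", "", "")

    @property
    def usable(self) -> bool:
        """True when downstream Wald inference is permitted."""
        return self.converged and not self.separation_flag

    def to_record(self) -> dict:
        """JSON-serialisable record (covariance as lower triangle)."""
        tril = self.cov[np.tril_indices(7)]
        return {
            "triplet": list(self.triplet),
            "beta": self.beta.tolist(),
            "cov_tril": tril.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "n_pairs": self.n_pairs,
            "n_discordant": self.n_discordant,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "TripletFit":
        cov = np.zeros((7, 7))
        cov[np.tril_indices(7)] = rec["cov_tril"]
        cov = cov + np.tril(cov, -1).T
        return cls(
            beta=np.asarray(rec["beta"], dtype=float),
            cov=cov,
            loglik=rec["loglik"],
            converged=rec["converged"],
            separation_flag=rec["separation_flag"],
            n_pairs=rec["n_pairs"],
            n_discordant=rec["n_discordant"],
            n_iter=-1,
            triplet=tuple(rec["triplet"]),
        )


@dataclass
class ContrastResult:
    """Wald inference for one linear combination of the coefficients."""

    label: str
    c: np.ndarray
    estimate: float
    se: float
    z: float
    p_one_sided: float


def conditional_loglik(beta: np.ndarray, design: TripletDesign) -> float:
    """Conditional log-likelihood of ``beta`` for 1:1 matched pairs.

    Concordant pairs each contribute ``log(1/2)``.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise DataError("beta must be finite")
    z = design.differences()
    return float(np.sum(log_expit(z @ beta)))


def fit_conditional_logit(z: np.ndarray) -> ConditionalFit:
    """Maximise the 1:1 conditional likelihood on difference rows ``z``.

    ``z`` is (n_pairs, p): case design row minus control design row per
    pair.  Raises :class:`FitError` when every pair is concordant and
    :class:`RankDeficiencyError` when the discordant rows are rank
    deficient (naming the aliased columns).
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    discordant = np.any(z != 0.0, axis=1)
    n_disc = int(discordant.sum())
    if n_disc == 0:
        raise FitError("no information: all pairs are concordant")
    zd = z[discordant]
    _check_rank(zd)

    beta = np.zeros(p)
    ll = float(np.sum(log_expit(zd @ beta)))
    converged = False
    n_iter = 0
    info = None
    for n_iter in range(1, MAX_ITER + 1):
        eta = zd @ beta
        prob = expit(eta)
        grad = zd.T @ (1.0 - prob)
        w = prob * (1.0 - prob)
        info = (zd * w[:, None]).T @ zd
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            _check_rank(zd)  # re-raise with column names if truly aliased
            raise FitError("information matrix became singular during fit")
        # step-halving: never accept a step that lowers the log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = float(np.sum(log_expit(zd @ cand)))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = float(np.sum(log_expit(zd @ beta)))
    else:
        eta = zd @ beta
        prob = expit(eta)
        grad = zd.T @ (1.0 - prob)
        w = prob * (1.0 - prob)
        info = (zd * w[:, None]).T @ zd
        converged = np.max(np.abs(grad)) < GRAD_TOL

    # |beta| beyond the bound means an odds ratio above e^15: in practice a
    # separated likelihood whose gradient only vanishes in the limit
    separation = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    cov = np.linalg.pinv(info) if separation else np.linalg.inv(info)
    # total log-likelihood includes the concordant pairs' constant terms
    ll_total = ll + (n - n_disc) * np.log(0.5)
    return ConditionalFit(
        beta=beta,
        cov=cov,
        loglik=ll_total,
        converged=converged,
        separation_flag=separation,
        n_pairs=n,
        n_discordant=n_disc,
        n_iter=n_iter,
    )


def _check_rank(zd: np.ndarray) -> None:
    p = zd.shape[1]
    rank = np.linalg.matrix_rank(zd)
    if rank < p:
        _, _, vt = np.linalg.svd(zd, full_matrices=True)
        null_rows = vt[rank:]
        aliased = np.unique(np.nonzero(np.abs(null_rows) > 1e-8)[1])
        names = [TERM_NAMES[j] if p == 7 else f"col{j}" for j in aliased]
        raise RankDeficiencyError(names)


def fit_clrm(design: TripletDesign) -> TripletFit:
    """Fit the 7-term conditional logistic model for one triplet."""
    base = fit_conditional_logit(design.differences())
    return TripletFit(
        beta=base.beta,
        cov=base.cov,
        loglik=base.loglik,
        converged=base.converged,
        separation_flag=base.separation_flag,
        n_pairs=base.n_pairs,
        n_discordant=base.n_discordant,
        n_iter=base.n_iter,
        triplet=design.triplet,
    )


def wald_contrast(fit: ConditionalFit, c: np.ndarray, label: str = "") -> ContrastResult:
    """One-sided Wald test of H0: c'beta <= 0 against c'beta > 0."""
    if not fit.converged or fit.separation_flag:
        raise FitError("contrast requested on an unconverged or separated fit")
    c = np.asarray(c, dtype=float)
    estimate = float(c @ fit.beta)
    var = float(c @ fit.cov @ c)
    se = np.sqrt(max(var, 0.0))
    if se == 0.0:
        raise DegenerateContrastError(f"contrast {label!r} has zero standard error")
    z = estimate / se
    return ContrastResult(
        label=label,
        c=c,
        estimate=estimate,
        se=se,
        z=z,
        p_one_sided=float(norm.sf(z)),
    )


def log_or_at(fit: ConditionalFit, x1: int, x2: int, x3: int) -> tuple[float, float]:
    """Log odds ratio (and SE) of dose configuration (x1,x2,x3) vs (0,0,0).

    The reference configuration returns (0.0, 0.0) exactly.
    """
    c = design_row(x1, x2, x3)
    if not c.any():
        return 0.0, 0.0
    res = wald_contrast(fit, c, label=f"{x1}{x2}{x3}")
    return res.estimate, res.se
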