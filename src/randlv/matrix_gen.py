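"""Random interaction-matrix generators for Lotka-Volterra communities.

All generators return an :class:`InteractionMatrix` whose coefficient matrix
``A = (a_ij)`` holds per-capita interaction effects: ``a_ij`` is the effect of
species *j* on the growth of species *i*.  Intraspecific regulation is scaled
to unity, ``a_ii = -1``, throughout.

Interspecific effects come in unordered pairs ``{i, j}``.  A pair is

* **mutualistic** (+/+): both ``a_ij > 0`` and ``a_ji > 0``,
* **exploitative** (+/-): opposite signs (e.g. consumer-resource),
* **competitive** (-/-): both negative,
* **absent**: both exactly zero.

The main generator follows the Chen-Cohen scheme: each pair is retained with
probability ``C`` (the connectance), retained pairs are declared mutualistic
with probability ``P`` and otherwise take the configured background type, and
every nonzero magnitude is an independent half-normal draw ``sigma * |N(0,1)|``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "PairType",
    "GenParams",
    "InteractionMatrix",
    "generate_chen_cohen",
    "generate_uniform",
    "generate_gaussian",
    "classify_pairs",
]

BACKGROUNDS = ("exploitative", "competitive", "random")


class PairType(enum.IntEnum):
    """Label of an unordered species pair."""

    ABSENT = 0
    MUTUALISTIC = 1
    EXPLOITATIVE = 2
    COMPETITIVE = 3


@dataclass(frozen=True)
class GenParams:
    """Parameters of a random community draw.

    Parameters
    ----------
    n : int
        Number of species (>= 2).
    P : float
        Proportion of retained pairs assigned mutualistic (+/+) type, in [0, 1].
    C : float
        Connectance: probability that an unordered pair interacts at all,
        in [0, 1].
    sigma : float
        Interaction-variability scale (>= 0).  Nonzero magnitudes are drawn
        as ``sigma * |N(0, 1)|``.
    m : float
        Mean interaction strength, used by the uniform and Gaussian
        generators (ignored by the Chen-Cohen scheme).
    background : str
        Type given to retained non-mutualistic pairs: ``"exploitative"``,
        ``"competitive"`` or ``"random"`` (independent random sign per entry).
    seed : int
        Seed of the single RNG used for the draw; same seed, same matrix.
    """

    n: int
    P: float = 0.0
    C: float = 1.0
    sigma: float = 0.0
    m: float = 0.0
    background: str = "exploitative"
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ParameterError(f"n must be an integer >= 2, got {self.n}")
        if not 0.0 <= self.P <= 1.0:
            raise ParameterError(f"P must lie in [0, 1], got {self.P}")
        if not 0.0 <= self.C <= 1.0:
            raise ParameterError(f"C must lie in [0, 1], got {self.C}")
        if self.sigma < 0.0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.background not in BACKGROUNDS:
            raise ParameterError(
                f"background must be one of {BACKGROUNDS}, got {self.background!r}"
            )

    def with_(self, **kwargs) -> "GenParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class InteractionMatrix:
    """An interaction matrix together with its generation metadata.

    Attributes
    ----------
    A : ndarray, shape (n, n)
        Coefficient matrix; diagonal is exactly -1.
    params : GenParams or None
        Parameters of the generating draw (None for matrices loaded without
        a sidecar).
    pair_types : ndarray of uint8, shape (n, n)
        Symmetric matrix of :class:`PairType` codes; the diagonal carries
        :attr:`PairType.ABSENT` and is not meaningful.
    """

    A: np.ndarray
    params: GenParams | None = None
    pair_types: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ParameterError(f"A must be square, got shape {self.A.shape}")
        if self.pair_types is None:
            self.pair_types = classify_pairs(self.A)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def pair_type(self, i: int, j: int) -> PairType:
        if i == j:
            raise ParameterError("pair types are defined for i != j only")
        return PairType(int(self.pair_types[i, j]))

    def retained_fraction(self) -> float:
        """Fraction of unordered pairs that interact (realised connectance)."""
        iu, ju = np.triu_indices(self.n, k=1)
        return float(np.mean(self.pair_types[iu, ju] != PairType.ABSENT))

    def mutualistic_fraction(self) -> float:
        """Fraction of *retained* pairs labelled mutualistic."""
        iu, ju = np.triu_indices(self.n, k=1)
        codes = self.pair_types[iu, ju]
        retained = codes != PairType.ABSENT
        if not retained.any():
            return float("nan")
        return float(np.mean(codes[retained] == PairType.MUTUALISTIC))


def classify_pairs(A: np.ndarray) -> np.ndarray:
    """Infer pair-type codes from the sign pattern of ``A``.

    Both entries zero -> absent; both positive -> mutualistic; both negative
    -> competitive; opposite signs -> exploitative.  A pair with exactly one
    zero entry (which the shipped generators produce with probability zero)
    is classified exploitative.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    codes = np.zeros((n, n), dtype=np.uint8)
    iu, ju = np.triu_indices(n, k=1)
    a, b = A[iu, ju], A[ju, iu]
    pair_codes = np.full(iu.shape, PairType.EXPLOITATIVE, dtype=np.uint8)
    pair_codes[(a == 0) & (b == 0)] = PairType.ABSENT
    pair_codes[(a > 0) & (b > 0)] = PairType.MUTUALISTIC
    pair_codes[(a < 0) & (b < 0)] = PairType.COMPETITIVE
    codes[iu, ju] = pair_codes
    codes[ju, iu] = pair_codes
    return codes


def generate_chen_cohen(params: GenParams) -> InteractionMatrix:
    """Draw a random community under the Chen-Cohen scheme.

    Unordered pairs are independently retained with probability ``params.C``
    (otherwise both entries are zero).  Retained pairs are mutualistic with
    probability ``params.P``; the rest take ``params.background`` type.  Each
    nonzero magnitude is an independent half-normal draw with scale
    ``params.sigma``; only the *signs* of a pair are coupled by its type.
    Exploitative pairs assign the +/- orientation uniformly at random.  The
    diagonal is -1.

    Notes
    -----
    With ``background="random"`` each background entry gets an independent
    uniform sign, so a background pair may realise a (+/+) pattern; such
    pairs are *labelled by their realised signs*.  The expectation of the
    mutualistic label fraction therefore equals ``P`` exactly only for the
    exploitative and competitive backgrounds.
    """
    n = params.n
    rng = np.random.default_rng(params.seed)
    iu, ju = np.triu_indices(n, k=1)
    npairs = iu.size

    keep = rng.random(npairs) < params.C
    mut = rng.random(npairs) < params.P
    mag_upper = params.sigma * np.abs(rng.standard_normal(npairs))
    mag_lower = params.sigma * np.abs(rng.standard_normal(npairs))
    orient = rng.random(npairs) < 0.5
    sign_rand_u = np.where(rng.random(npairs) < 0.5, 1.0, -1.0)
    sign_rand_l = np.where(rng.random(npairs) < 0.5, 1.0, -1.0)

    sign_u = np.ones(npairs)
    sign_l = np.ones(npairs)
    bg = ~mut
    if params.background == "exploitative":
        sign_u[bg] = np.where(orient[bg], 1.0, -1.0)
        sign_l[bg] = -sign_u[bg]
    elif params.background == "competitive":
        sign_u[bg] = -1.0
        sign_l[bg] = -1.0
    else:  # random: independent mean-zero signs per entry
        sign_u[bg] = sign_rand_u[bg]
        sign_l[bg] = sign_rand_l[bg]

    A = -np.eye(n)
    A[iu, ju] = np.where(keep, sign_u * mag_upper, 0.0)
    A[ju, iu] = np.where(keep, sign_l * mag_lower, 0.0)

    im = InteractionMatrix(A=A, params=params, pair_types=classify_pairs(A))
    # Degenerate zero-magnitude draws (sigma == 0) leave retained pairs with
    # zero entries; the sign-pattern classification already records them as
    # absent, which keeps the pair_type/sign invariant intact.
    return im


def generate_uniform(
    n: int, m: float, C: float = 1.0, P: float = 1.0
) -> InteractionMatrix:
    """Deterministic 'uniform model' skeleton: selected pairs share strength m.

    A fraction ``C * P`` of unordered pairs (the first ``round(C*P*n(n-1)/2)``
    in row-major upper-triangular order — a deterministic stand-in for the
    expectation) receive ``a_ij = a_ji = m``; everything else is zero off the
    diagonal, and the diagonal is -1.  With ``C = P = 1`` every off-diagonal
    entry equals ``m``, the 'regular model'.
    """
    params = GenParams(n=n, P=P, C=C, sigma=0.0, m=m)
    iu, ju = np.triu_indices(n, k=1)
    k = int(round(C * P * iu.size))
    A = -np.eye(n)
    A[iu[:k], ju[:k]] = m
    A[ju[:k], iu[:k]] = m
    return InteractionMatrix(A=A, params=params, pair_types=classify_pairs(A))


def generate_gaussian(
    n: int,
    m: float,
    sigma: float,
    C: float = 1.0,
    positive_only: bool = False,
    seed: int = 0,
) -> InteractionMatrix:
    """Gaussian-mean generator: off-diagonal entries ~ Normal(m, sigma).

    If ``positive_only``, non-positive draws are redrawn until positive
    (truncation at zero), which requires ``m > 0``.  Pairs are removed with
    probability ``1 - C`` (both entries zeroed together).  Pair labels are
    classified from the realised sign pattern.
    """
    if positive_only and m <= 0:
        raise ParameterError("positive_only requires m > 0")
    params = GenParams(n=n, P=1.0 if positive_only else 0.0, C=C, sigma=sigma,
                       m=m, background="random", seed=seed)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < C

    vals = rng.normal(m, sigma, size=(n, n))
    if positive_only and sigma > 0:
        offdiag = ~np.eye(n, dtype=bool)
        bad = (vals <= 0) & offdiag
        while bad.any():
            vals[bad] = rng.normal(m, sigma, size=int(bad.sum()))
            bad = (vals <= 0) & offdiag

    A = -np.eye(n)
    A[iu, ju] = np.where(keep, vals[iu, ju], 0.0)
    A[ju, iu] = np.where(keep, vals[ju, iu], 0.0)
    return InteractionMatrix(A=A, params=params, pair_types=classify_pairs(A))
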