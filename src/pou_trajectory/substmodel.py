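"""Amino-acid substitution models: LG exchangeabilities + discrete-gamma rates.

The model is a general time-reversible CTMC over the 20 amino acids.
Given a symmetric exchangeability matrix S and equilibrium frequencies
pi, the instantaneous rate matrix is Q_ij = S_ij * pi_j (i != j), with
the diagonal set so rows sum to zero and the whole matrix rescaled so
that one unit of branch length equals one expected substitution per
site at stationarity:  -sum_i pi_i Q_ii = 1.

Rate heterogeneity across sites uses Yang's discrete-gamma scheme:
k equal-probability categories of a Gamma(alpha, 1/alpha) distribution
(mean 1), each category represented by its conditional mean rate.

The LG matrix (Le & Gascuel 2008) ships with the package as a
PAML-style text table; a Poisson (equal-rates, equal-frequency) model
is available for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .io import AMINO_ACIDS

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def load_paml_dat(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-style .dat model file.

    Layout: 19 lines of the lower triangle of the symmetric
    exchangeability matrix (row i holds S[i, 0..i-1] for i = 1..19,
    amino acids in PAML order A R N D C Q E G H I L K M F P S T W Y V),
    then a blank line, then the 20 equilibrium frequencies.
    """
    numbers: list[float] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        row: list[float] = []
        for tok in parts:
            try:
                row.append(float(tok))
            except ValueError:
                row = []
                break
        numbers.extend(row)
    need = 190 + 20
    if len(numbers) < need:
        raise ValueError(f"{path}: expected at least {need} numbers, found {len(numbers)}")
    tri, freqs = numbers[:190], np.array(numbers[190:210])
    S = np.zeros((N_STATES, N_STATES))
    pos = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = tri[pos]
            pos += 1
    freqs = freqs / freqs.sum()
    return S, freqs


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Normalized reversible rate matrix from exchangeabilities and frequencies."""
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ValueError(f"S must be {N_STATES}x{N_STATES}")
    if not np.allclose(S, S.T):
        raise ValueError("exchangeability matrix must be symmetric")
    if np.any(S < 0):
        raise ValueError("exchangeabilities must be non-negative")
    if pi.shape != (N_STATES,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a probability vector of length 20")
    if np.any(pi == 0):
        raise ValueError("states with zero equilibrium frequency are unsupported")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
    scale = -np.sum(pi * np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, 1/alpha).

    Category means (not medians) are used, and the rates are renormalized
    to average exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one rate category, got {k}")
    if k == 1:
        return np.array([1.0])
    # quantile boundaries of the mean-1 gamma (shape alpha, scale 1/alpha)
    probs = np.arange(1, k) / k
    bounds = np.concatenate([[0.0], gamma_dist.ppf(probs, alpha, scale=1.0 / alpha), [np.inf]])
    # E[X | a < X < b] * P(a < X < b) = P(shape alpha+1 in (a,b)) for mean-1 gamma
    upper = gammainc(alpha + 1.0, bounds[1:] * alpha)
    lower = gammainc(alpha + 1.0, bounds[:-1] * alpha)
    rates = (upper - lower) * k
    rates = np.maximum(rates, 1e-12)
    rates = rates / rates.mean()
    return rates


@dataclass
class RateModel:
    """A reversible substitution model with discrete-gamma rate heterogeneity."""

    name: str
    exchangeabilities: np.ndarray
    equilibrium_freqs: np.ndarray
    gamma_shape: float = 1.0
    n_categories: int = 4

    Q: np.ndarray = field(init=False, repr=False)
    category_rates: np.ndarray = field(init=False, repr=False)
    # spectral decomposition of the pi^(1/2) similarity transform of Q;
    # numerically stable for reversible models and reused for every P(t)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.equilibrium_freqs = np.asarray(self.equilibrium_freqs, dtype=float)
        self.Q = build_rate_matrix(self.exchangeabilities, self.equilibrium_freqs)
        self.category_rates = discretize_gamma(self.gamma_shape, self.n_categories)
        sqrt_pi = np.sqrt(self.equilibrium_freqs)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)  # symmetrize against round-off
        w, U = np.linalg.eigh(B)
        self._eigvals = w
        self._left = U / sqrt_pi[:, None]
        self._right = U.T * sqrt_pi[None, :]

    @property
    def pi(self) -> np.ndarray:
        return self.equilibrium_freqs

    def with_gamma(self, alpha: float, k: Optional[int] = None) -> "RateModel":
        return RateModel(
            self.name,
            self.exchangeabilities,
            self.equilibrium_freqs,
            gamma_shape=alpha,
            n_categories=self.n_categories if k is None else k,
        )

    def transition_probabilities(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        if rate <= 0:
            raise ValueError(f"rate must be positive, got {rate}")
        P = (self._left * np.exp(self._eigvals * (t * rate))) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(Q: np.ndarray, t: float, rate: float = 1.0) -> np.ndarray:
    """Matrix exponential P = exp(Q * rate * t) for an arbitrary rate matrix.

    Free-function form used when Q does not come from a RateModel; for a
    reversible Q the RateModel method is preferred (spectral, cheaper).
    """
    from scipy.linalg import expm

    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    P = expm(Q * (t * rate))
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _lg_tables() -> tuple[np.ndarray, np.ndarray]:
    with resources.as_file(resources.files("pou_trajectory.data") / "lg.dat") as p:
        return load_paml_dat(p)


def get_model(
    name: str = "LG",
    *,
    gamma_shape: float = 1.0,
    n_categories: int = 4,
    custom_dat: Optional[str | Path] = None,
    empirical_freqs: Optional[np.ndarray] = None,
) -> RateModel:
    """Construct a named model ("LG", "POISSON") or load a PAML .dat file.

    ``empirical_freqs`` substitutes observed frequencies for the model's
    own (the "+F" variant); off by default.
    """
    name = name.upper()
    if custom_dat is not None:
        S, pi = load_paml_dat(custom_dat)
    elif name == "LG":
        S, pi = _lg_tables()
    elif name == "POISSON":
        S = np.ones((N_STATES, N_STATES))
        np.fill_diagonal(S, 0.0)
        pi = np.full(N_STATES, 1.0 / N_STATES)
    else:
        raise ValueError(f"unknown model {name!r}; use 'LG', 'POISSON' or custom_dat")
    if empirical_freqs is not None:
        pi = np.asarray(empirical_freqs, dtype=float)
        pi = pi / pi.sum()
    return RateModel(name, S, pi, gamma_shape=gamma_shape, n_categories=n_categories)
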