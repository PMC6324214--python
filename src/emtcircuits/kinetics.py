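"""Regulatory kernels and kinetic parameter sets.

Three kernels drive every circuit in this package:

* the *shifted Hill function* ``H(X) = (1 + lam*(X/X0)**n) / (1 + (X/X0)**n)``
  used for transcriptional and non-transcriptional regulation (equal to 1 at
  zero input and to the fold-change ``lam`` at saturation; ``lam > 1`` is
  activation, ``lam < 1`` inhibition);
* a *microRNA silencing* kernel describing an mRNA with ``n`` microRNA binding
  sites: the occupancy of ``i`` sites is binomial in ``mu/(mu0+mu)``, and the
  occupancy-weighted sums give the residual translation rate ``L(mu)``, the
  microRNA-dependent mRNA degradation ``Ym(mu)`` and the microRNA turnover
  ``Ymu(mu)`` (each degraded complex consumes its bound microRNAs);
* a *splicing partition* splitting a total CD44 production rate between the
  standard (CD44s) and variant (CD44v) isoforms as a monotone sigmoid function
  of the splicing regulator ESRP1.

A :class:`KineticParameterSet` is a flat, named mapping of every rate constant
of one model instance, with structured accessors for the kernels above and a
bit-exact ``name value`` text-file round trip.

Parameter naming convention (species names contain no underscores):

=====================  ====================================================
``g_<sp>``             production (molecules/h); translation rate per mRNA
                       for proteins with a template
``k_<sp>``             degradation (1/h)
``h_<src>_<tgt>_X0``   Hill threshold (molecules; molecules^2 for cofactor-
                       gated edges), ``_n`` coefficient, ``_lam`` fold-change
``g_C``                total CD44 production split by the splicing partition
``spl_X0``, ``spl_n``  ESRP1 splicing threshold and coefficient
``mir_<src>_<tgt>_*``  silencing block: ``mu0``, ``sites``, ``l1..``, ``gm1..``,
                       ``gu1..`` (``l0 = 1`` and ``gm0 = gu0 = 0`` implicit)
=====================  ====================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np


class ConfigurationError(ValueError):
    """Missing, orphan, or inconsistent kinetic parameters."""


# ---------------------------------------------------------------------------
# shifted Hill
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillRegulation:
    """Shifted-Hill parameters of one regulatory edge."""

    threshold: float   # X0, molecules
    coefficient: float  # n >= 1 (integer in the shipped defaults)
    fold_change: float  # lam > 0; > 1 activation, < 1 inhibition

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("Hill threshold X0 must be > 0")
        if self.coefficient < 1:
            raise ConfigurationError("Hill coefficient n must be >= 1")
        if self.fold_change <= 0:
            raise ConfigurationError("fold change lam must be > 0")

    def __call__(self, X):
        return shifted_hill(X, self)


def shifted_hill(X, reg: HillRegulation):
    """Shifted Hill factor ``(1 + lam*(X/X0)**n) / (1 + (X/X0)**n)``.

    Bounded between ``min(1, lam)`` and ``max(1, lam)``; equals 1 at ``X = 0``
    and tends to ``lam`` as ``X -> inf``.  Accepts scalars or arrays.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("regulator level X must be >= 0")
    return _hill_factor(X, reg.threshold, reg.coefficient, reg.fold_change)


def _hill_factor(X, X0, n, lam):
    """Unchecked vectorized shifted-Hill core (inputs clipped at 0).

    ``u`` is capped at 1e30, at which point the factor equals ``lam`` to
    machine precision, so saturation never produces inf/inf.
    """
    u = (np.maximum(X, 0.0) / X0) ** n
    u = np.minimum(u, 1e30)
    return (1.0 + lam * u) / (1.0 + u)


# ---------------------------------------------------------------------------
# microRNA silencing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroRNASilencing:
    """MicroRNA binding/silencing parameters for one microRNA-mRNA pair.

    ``l``/``gamma_m``/``gamma_mu`` have length ``n_sites + 1`` with the fixed
    leading entries ``l[0] = 1`` (full translation with nothing bound) and
    ``gamma_m[0] = gamma_mu[0] = 0`` (no silencing losses with nothing bound).
    """

    mu0: float          # binding threshold, molecules
    n_sites: int
    l: tuple            # translation factors, nonincreasing
    gamma_m: tuple      # mRNA degradation weights (1/h), nondecreasing
    gamma_mu: tuple     # microRNA turnover weights (1/h), nondecreasing

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ConfigurationError("binding threshold mu0 must be > 0")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        for name, vec in (("l", self.l), ("gamma_m", self.gamma_m), ("gamma_mu", self.gamma_mu)):
            if len(vec) != self.n_sites + 1:
                raise ConfigurationError(
                    f"{name} must have length n_sites+1 = {self.n_sites + 1}, got {len(vec)}"
                )
            arr = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ConfigurationError(f"{name} entries must be finite and >= 0")
        if self.l[0] != 1.0:
            raise ConfigurationError("l[0] must equal 1")
        if self.gamma_m[0] != 0.0 or self.gamma_mu[0] != 0.0:
            raise ConfigurationError("gamma_m[0] and gamma_mu[0] must equal 0")


def mirna_bound_fraction(mu, sil: MicroRNASilencing):
    """Occupancy probabilities ``M_0..M_n`` of a microRNA-target mRNA.

    ``M_i = C(n, i) * (mu/mu0)**i / (1 + mu/mu0)**n`` — a binomial law with
    per-site occupancy ``p = mu / (mu0 + mu)``; the entries sum to 1.  Returns
    shape ``mu.shape + (n_sites + 1,)``.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("microRNA level mu must be >= 0")
    return _bound_fraction(mu, sil.mu0, sil.n_sites)


def _bound_fraction(mu, mu0, n):
    p = mu / (mu0 + mu)
    q = 1.0 - p
    i = np.arange(n + 1)
    coeff = np.array([math.comb(n, k) for k in range(n + 1)], dtype=float)
    return coeff * p[..., None] ** i * q[..., None] ** (n - i)


def mirna_modulation(mu, sil: MicroRNASilencing):
    """Occupancy-weighted silencing factors ``(L, Ym, Ymu)``.

    ``L = sum l_i M_i`` (residual translation, nonincreasing in ``mu``),
    ``Ym = sum gamma_m_i M_i`` (microRNA-dependent mRNA degradation rate) and
    ``Ymu = sum i * gamma_mu_i M_i`` (microRNA turnover rate; degrading a
    complex with ``i`` bound microRNAs consumes ``i`` of them).  ``L(0) = 1``,
    ``Ym(0) = Ymu(0) = 0``.
    """
    M = mirna_bound_fraction(mu, sil)
    l = np.asarray(sil.l, dtype=float)
    gm = np.asarray(sil.gamma_m, dtype=float)
    gu = np.asarray(sil.gamma_mu, dtype=float)
    i = np.arange(sil.n_sites + 1, dtype=float)
    L = M @ l
    Ym = M @ gm
    Ymu = M @ (i * gu)
    return L, Ym, Ymu


# ---------------------------------------------------------------------------
# splicing partition
# ---------------------------------------------------------------------------

def _splicing_core(E1, X0, n):
    u = (np.maximum(E1, 0.0) / X0) ** n
    u = np.minimum(u, 1e30)
    return u / (1.0 + u)


def splicing_fraction(E1, X0, n):
    """Variant-isoform fraction ``f(E1) = (E1/X0)**n / (1 + (E1/X0)**n)``.

    Monotone increasing: high ESRP1 routes CD44 production toward CD44v,
    low ESRP1 toward CD44s.
    """
    E1 = np.asarray(E1, dtype=float)
    if np.any(E1 < 0):
        raise ValueError("ESRP1 level must be >= 0")
    return _splicing_core(E1, X0, n)


def splicing_partition(E1, g_C, X0, n):
    """Split total CD44 production: returns ``(rate_CD44s, rate_CD44v)``.

    ``rate_s + rate_v = g_C`` exactly; at ``E1 = X0`` the split is equal.
    """
    f = splicing_fraction(E1, X0, n)
    return g_C * (1.0 - f), g_C * f


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass
class KineticParameterSet:
    """Flat named mapping of every kinetic parameter of one model instance."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        try:
            return self.values[key]
        except KeyError:
            raise ConfigurationError(f"missing kinetic parameter {key!r}") from None

    def __setitem__(self, key: str, value: float) -> None:
        self.values[key] = float(value)

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, KineticParameterSet) and self.values == other.values

    def copy(self) -> "KineticParameterSet":
        return KineticParameterSet(dict(self.values))

    # -- structured accessors ------------------------------------------------

    def hill(self, source: str, target: str) -> HillRegulation:
        base = f"h_{source}_{target}"
        return HillRegulation(
            threshold=self[f"{base}_X0"],
            coefficient=self[f"{base}_n"],
            fold_change=self[f"{base}_lam"],
        )

    def silencing(self, source: str, target: str) -> MicroRNASilencing:
        base = f"mir_{source}_{target}"
        n = int(round(self[f"{base}_sites"]))
        l = (1.0,) + tuple(self[f"{base}_l{i}"] for i in range(1, n + 1))
        gm = (0.0,) + tuple(self[f"{base}_gm{i}"] for i in range(1, n + 1))
        gu = (0.0,) + tuple(self[f"{base}_gu{i}"] for i in range(1, n + 1))
        return MicroRNASilencing(mu0=self[f"{base}_mu0"], n_sites=n, l=l, gamma_m=gm, gamma_mu=gu)

    # -- file I/O -------------------------------------------------------------

    @classmethod
    def from_file(cls, path) -> "KineticParameterSet":
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ConfigurationError(f"{Path(path).name}:{lineno}: expected 'name value'")
            try:
                values[tokens[0]] = float(tokens[1])
            except ValueError:
                raise ConfigurationError(
                    f"{Path(path).name}:{lineno}: non-numeric value {tokens[1]!r}"
                ) from None
        return cls(values)

    def to_file(self, path) -> None:
        lines = [f"{k} {float(v)!r}" for k, v in self.values.items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "KineticParameterSet":
        return cls({k: float(v) for k, v in mapping.items()})
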