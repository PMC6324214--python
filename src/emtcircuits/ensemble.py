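"""Random-parameter ensemble analysis (random circuit perturbation style).

For a fixed topology, an ensemble samples many complete kinetic parameter
sets from documented ranges, collects every stable steady state of every
sampled model, labels each solution epithelial / hybrid / mesenchymal from
z-scored ZEB1-mRNA and miR-200 log-levels, and compares phenotype frequencies
between a control topology and link-knockout topologies across replicates
with a paired two-tailed t test.

Sampling conventions (per parameter class, all in config, not code):
production uniform on [1, 100] molecules/h; degradation uniform on
[0.1, 1]/h; Hill coefficients integer-uniform on [1, 6]; fold-changes
uniform on [1, 100], inverted (1/x) for inhibitions; thresholds by the
*half-functional rule* — uniform over (0.02, 1.98) times the regulator's
characteristic level, so the regulation has an even chance of being active.
MicroRNA-silencing shape vectors (l, gamma) are structural and kept at the
published defaults; the binding threshold is sampled half-functionally.
"""

from __future__ import annotations

import logging
import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .circuit import RegulatoryCircuit
from .kinetics import ConfigurationError, KineticParameterSet
from .model import build_rhs
from .presets import ZEB_MRNA
from .steady import PHENOTYPES, find_steady_states

MIR200 = "u200"

#: the three link knockouts studied on the CD44 reduction
KNOCKOUTS = {
    "ZEB1-ESRP1": ("Z", "E1"),
    "ESRP1-CD44s": ("E1", "Cs"),
    "CD44s-ZEB1": ("Cs", "mZ"),
}

#: published microRNA-silencing shape vectors (6 binding sites)
DEFAULT_SILENCING_SHAPE = {
    "sites": 6,
    "l": (0.6, 0.3, 0.1, 0.05, 0.05, 0.05),
    "gm": (0.04, 0.2, 1.0, 1.0, 1.0, 1.0),
    "gu": (0.005, 0.05, 0.5, 0.5, 0.5, 0.5),
}


@dataclass(frozen=True)
class SamplingRanges:
    """Sampling intervals per kinetic-parameter class."""

    production: tuple[float, float] = (1.0, 100.0)
    degradation: tuple[float, float] = (0.1, 1.0)
    hill_coefficient: tuple[int, int] = (1, 6)
    fold_change: tuple[float, float] = (1.0, 100.0)
    threshold_span: tuple[float, float] = (0.02, 1.98)  # × regulator median level
    silencing_shape: dict = field(default_factory=lambda: dict(DEFAULT_SILENCING_SHAPE))

    def __post_init__(self) -> None:
        for name in ("production", "degradation", "fold_change", "threshold_span"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi) or not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValueError(f"{name} interval must be positive and finite")

    def median_level(self) -> float:
        """Characteristic level g~/k~ of an unregulated sampled species."""
        g = 0.5 * (self.production[0] + self.production[1])
        k = 0.5 * (self.degradation[0] + self.degradation[1])
        return g / k


def _median_edge_factors(ranges: SamplingRanges, n_draws: int = 8192,
                         seed: int = 987654321) -> tuple[float, float]:
    """Median shifted-Hill factor of a sampled activation / inhibition edge.

    Because thresholds are drawn proportionally to the regulator's median
    level, the factor ``H(M; X0 = u*M, n, lam)`` evaluated at that level is
    scale-free: its distribution depends only on the sampling ranges.  The
    medians are computed once by deterministic Monte Carlo.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(*ranges.threshold_span, n_draws)
    n = rng.integers(ranges.hill_coefficient[0], ranges.hill_coefficient[1] + 1, n_draws)
    lam = rng.uniform(*ranges.fold_change, n_draws)
    v = (1.0 / u) ** n
    act = float(np.median((1.0 + lam * v) / (1.0 + v)))
    inh = float(np.median((1.0 + v / lam) / (1.0 + v)))
    return act, inh


def _silencing_median_factors(ranges: SamplingRanges) -> tuple[float, float]:
    """(translation factor L, mRNA degradation rate Ym) at half occupancy.

    With the binding threshold half-functional, the microRNA sits near its
    threshold, i.e. each site is bound with probability 1/2.
    """
    shape = ranges.silencing_shape
    n = shape["sites"]
    w = np.array([math.comb(n, i) for i in range(n + 1)], dtype=float) / 2.0 ** n
    L = float(w @ np.array((1.0,) + tuple(shape["l"])))
    Ym = float(w @ np.array((0.0,) + tuple(shape["gm"])))
    return L, Ym


def _species_level_scales(circuit: RegulatoryCircuit, ranges: SamplingRanges) -> dict:
    """Self-consistent median level per species under the sampling ranges.

    The unregulated median ``g~/k~`` is corrected by the median factor of
    every incoming regulation (activation boosts, inhibition and microRNA
    silencing suppress, splicing halves, translation couples to the template
    mRNA), so half-functional thresholds land where the regulator actually
    lives, not where it would sit unregulated.
    """
    base = ranges.median_level()
    k_med = 0.5 * (ranges.degradation[0] + ranges.degradation[1])
    f_act, f_inh = _median_edge_factors(ranges)
    L0, Ym0 = _silencing_median_factors(ranges)
    scales: dict[str, float] = {}
    for sp in circuit.species:
        incoming = circuit.edges_into(sp.name)
        spliced = any(e.mode == "splicing" for e in incoming)
        level = 0.5 * base if spliced else base
        for e in incoming:
            if e.mode in ("transcriptional", "nontranscriptional"):
                level *= f_act if e.sign == "activation" else f_inh
            elif e.mode == "microRNA_translational":
                level *= k_med / (k_med + Ym0)
        scales[sp.name] = level
    # translation-coupled proteins: g/k per mRNA times the template level,
    # damped by the residual translation of silenced templates
    for sp in circuit.species:
        if sp.template is not None:
            level = base * scales[sp.template]
            for e in circuit.edges_into(sp.template):
                if e.mode == "microRNA_translational":
                    level *= L0
            scales[sp.name] = level
    return scales


def sample_parameters(
    circuit: RegulatoryCircuit,
    ranges: SamplingRanges,
    rng: np.random.Generator,
    snail_level: Optional[float] = None,
    levels: Optional[dict] = None,
) -> KineticParameterSet:
    """One complete random parameter set for ``circuit``.

    Deterministic given the generator state; thresholds follow the
    half-functional rule against the regulator's expected median level
    (``snail_level`` for control-parameter edges).  ``levels`` may carry the
    precomputed :func:`_species_level_scales` (they depend only on the
    topology and ranges).
    """
    if levels is None:
        levels = _species_level_scales(circuit, ranges)
    p: dict[str, float] = {}
    has_splicing = any(e.mode == "splicing" for e in circuit.edges)
    for sp in circuit.species:
        spliced = any(e.mode == "splicing" for e in circuit.edges_into(sp.name))
        if not spliced:
            p[f"g_{sp.name}"] = rng.uniform(*ranges.production)
        p[f"k_{sp.name}"] = rng.uniform(*ranges.degradation)
    if has_splicing:
        p["g_C"] = rng.uniform(*ranges.production)
        e1 = next(e.source for e in circuit.edges if e.mode == "splicing")
        p["spl_X0"] = levels[e1] * rng.uniform(*ranges.threshold_span)
        p["spl_n"] = float(rng.integers(ranges.hill_coefficient[0],
                                        ranges.hill_coefficient[1] + 1))
    for e in circuit.edges:
        if e.mode in ("transcriptional", "nontranscriptional"):
            if e.source == circuit.control_parameter:
                if snail_level is None or snail_level <= 0:
                    raise ConfigurationError(
                        "sampling a control-parameter edge needs a positive snail_level")
                m = snail_level
            else:
                m = levels[e.source]
            if e.cofactor is not None:
                m = m * levels[e.cofactor]
            base = f"h_{e.source}_{e.target}"
            p[f"{base}_X0"] = m * rng.uniform(*ranges.threshold_span)
            p[f"{base}_n"] = float(rng.integers(ranges.hill_coefficient[0],
                                                ranges.hill_coefficient[1] + 1))
            lam = rng.uniform(*ranges.fold_change)
            p[f"{base}_lam"] = lam if e.sign == "activation" else 1.0 / lam
        elif e.mode == "microRNA_translational":
            shape = ranges.silencing_shape
            base = f"mir_{e.source}_{e.target}"
            p[f"{base}_mu0"] = levels[e.source] * rng.uniform(*ranges.threshold_span)
            p[f"{base}_sites"] = float(shape["sites"])
            for i, (l, gm, gu) in enumerate(zip(shape["l"], shape["gm"], shape["gu"]), start=1):
                p[f"{base}_l{i}"] = l
                p[f"{base}_gm{i}"] = gm
                p[f"{base}_gu{i}"] = gu
    return KineticParameterSet(p)


def apply_knockout(circuit: RegulatoryCircuit, source: str, target: str) -> RegulatoryCircuit:
    """Circuit with the ``source -> target`` link deleted.

    In the assembled right-hand side the removed regulatory factor is
    identically neutral (Hill factor 1; a knocked-out splicing link leaves a
    constitutive half share of total CD44 production; a knocked-out silencing
    link removes translation repression and the silencing losses).  Knocking
    out an absent edge — including the same edge twice — raises
    :class:`ConfigurationError`.
    """
    try:
        return circuit.without_edge(source, target)
    except KeyError:
        raise ConfigurationError(
            f"cannot knock out {source}->{target}: edge not present in "
            f"circuit {circuit.name!r}") from None


@dataclass
class EnsembleResult:
    """Stable solutions and phenotype frequencies of one sampled ensemble."""

    circuit_name: str
    seed: int
    n_models: int
    n_replicates: int
    solutions: pd.DataFrame        # replicate, model, per-species levels
    frequencies: pd.DataFrame      # replicate × phenotype fractions (own stats)
    stats: pd.DataFrame            # per-species mean/sd of log10 levels (pooled)
    n_excluded: int                # models with no converged stable state
    species_names: list[str] = field(default_factory=list)


def ensemble_statistics(solutions: pd.DataFrame, species: Sequence[str]) -> pd.DataFrame:
    """Pooled mean/sd of log10 levels per species over all stable solutions."""
    logs = np.log10(solutions[list(species)].to_numpy() + 1e-12)
    return pd.DataFrame({"mean": logs.mean(axis=0), "sd": logs.std(axis=0, ddof=0)},
                        index=list(species))


def classify_ensemble_solution(solution, stats: pd.DataFrame, z_star: float = 0.5,
                               zeb: str = ZEB_MRNA, mirna: str = MIR200) -> str:
    """E / hybrid / M from z-scored ZEB1-mRNA and miR-200 log-levels.

    Epithelial: ZEB1 below and miR-200 above the ensemble mean by more than
    ``z_star`` standard deviations; mesenchymal: the reverse; anything else
    (including the pooled mean itself) is hybrid.
    """
    for name in (zeb, mirna):
        if stats.loc[name, "sd"] <= 0:
            raise ValueError(f"degenerate ensemble: zero variance in {name}")
    zz = (math.log10(float(solution[zeb]) + 1e-12) - stats.loc[zeb, "mean"]) / stats.loc[zeb, "sd"]
    zu = (math.log10(float(solution[mirna]) + 1e-12) - stats.loc[mirna, "mean"]) / stats.loc[mirna, "sd"]
    if zz < -z_star and zu > z_star:
        return "E"
    if zz > z_star and zu < -z_star:
        return "M"
    return "hybrid"


def label_solutions(solutions: pd.DataFrame, stats: pd.DataFrame,
                    z_star: float = 0.5) -> pd.Series:
    """Vectorized phenotype labels for a solutions table."""
    for name in (ZEB_MRNA, MIR200):
        if stats.loc[name, "sd"] <= 0:
            raise ValueError(f"degenerate ensemble: zero variance in {name}")
    zz = (np.log10(solutions[ZEB_MRNA].to_numpy() + 1e-12) - stats.loc[ZEB_MRNA, "mean"]) / stats.loc[ZEB_MRNA, "sd"]
    zu = (np.log10(solutions[MIR200].to_numpy() + 1e-12) - stats.loc[MIR200, "mean"]) / stats.loc[MIR200, "sd"]
    labels = np.full(len(solutions), "hybrid", dtype=object)
    labels[(zz < -z_star) & (zu > z_star)] = "E"
    labels[(zz > z_star) & (zu < -z_star)] = "M"
    return pd.Series(labels, index=solutions.index, name="phenotype")


def phenotype_frequencies(solutions: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-replicate E/hybrid/M fractions (rows sum to 1)."""
    df = solutions.assign(phenotype=labels)
    out = (df.groupby("replicate")["phenotype"]
             .value_counts(normalize=True)
             .unstack(fill_value=0.0))
    for ph in PHENOTYPES:
        if ph not in out.columns:
            out[ph] = 0.0
    return out[list(PHENOTYPES)]


def run_ensemble(
    circuit: RegulatoryCircuit,
    n_models: int,
    n_replicates: int = 3,
    seed: int = 0,
    ranges: Optional[SamplingRanges] = None,
    snail: Optional[float] = None,
    n_starts: int = 100,
    t_pre: float = 16.0,
    dt_pre: float = 0.4,
    z_star: float = 0.5,
) -> EnsembleResult:
    """Sample ``n_models`` random models per replicate and collect all stable
    steady states found by the multistart solver.

    Fully determined by ``(circuit, ranges, seed, solver settings)``; models
    whose search converges to no stable state are excluded and counted.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    ranges = ranges or SamplingRanges()
    species = circuit.species_names
    rows = []
    n_excluded = 0
    root = np.random.SeedSequence(seed)
    levels = _species_level_scales(circuit, ranges)
    for rep, rep_seq in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(rep_seq)
        for m in range(n_models):
            params = sample_parameters(circuit, ranges, rng, snail_level=snail,
                                       levels=levels)
            rhs = build_rhs(circuit, params, snail=snail or 0.0)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # exclusions are counted below
                states = find_steady_states(
                    rhs, n_starts=n_starts, seed=int(rng.integers(2**31)),
                    pre_integrate=True, t_pre=t_pre, dt_pre=dt_pre,
                    start_hi=300.0, newton_from_raw=False, max_iter=40,
                )
            stable = [s for s in states if s.stable]
            if not stable:
                n_excluded += 1
                continue
            for s in stable:
                rows.append((rep, m, *s.state))
    if n_excluded:
        logging.getLogger(__name__).info(
            "ensemble %s: %d/%d models excluded (no converged stable state)",
            circuit.name, n_excluded, n_models * n_replicates)
    solutions = pd.DataFrame(rows, columns=["replicate", "model", *species])
    if solutions.empty:
        raise RuntimeError("ensemble produced no stable solutions")
    stats = ensemble_statistics(solutions, species)
    labels = label_solutions(solutions, stats, z_star=z_star)
    freqs = phenotype_frequencies(solutions, labels)
    return EnsembleResult(
        circuit_name=circuit.name,
        seed=seed,
        n_models=n_models,
        n_replicates=n_replicates,
        solutions=solutions,
        frequencies=freqs,
        stats=stats,
        n_excluded=n_excluded,
        species_names=list(species),
    )


def paired_t(diff: np.ndarray) -> tuple[float, float, bool]:
    """Two-tailed paired t statistic on replicate differences.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``df = n - 1``.  A zero-variance
    difference vector is degenerate: returns ``(0, nan, True)`` when all
    differences are 0, ``(±inf, 0, True)`` otherwise.
    """
    d = np.asarray(diff, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t test needs at least 2 replicates")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return 0.0, float("nan"), True
        return math.copysign(float("inf"), d.mean()), 0.0, True
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def compare_conditions(control: EnsembleResult, ko: EnsembleResult,
                       z_star: float = 0.5) -> pd.DataFrame:
    """Per-phenotype frequency difference (KO − control) with paired t test.

    Knockout solutions are re-labeled against the *control* ensemble
    statistics so the frequency axes are comparable across conditions;
    control labels are unchanged by construction.
    """
    if control.n_replicates != ko.n_replicates:
        raise ValueError("conditions must have equal replicate counts")
    f_ctrl = phenotype_frequencies(
        control.solutions, label_solutions(control.solutions, control.stats, z_star))
    f_ko = phenotype_frequencies(
        ko.solutions, label_solutions(ko.solutions, control.stats, z_star))
    rows = []
    for ph in PHENOTYPES:
        d = f_ko[ph].to_numpy() - f_ctrl[ph].to_numpy()
        t, p, degenerate = paired_t(d)
        rows.append({
            "phenotype": ph,
            "control_mean": f_ctrl[ph].mean(),
            "ko_mean": f_ko[ph].mean(),
            "difference": d.mean(),
            "t": t,
            "p": p,
            "df": control.n_replicates - 1,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def pca_project(solutions: pd.DataFrame, species: Optional[Sequence[str]] = None,
                n_components: int = 2):
    """PCA of standardized log10 solution levels.

    Returns ``(coordinates, explained_variance_ratio)``; rank-deficient input
    simply yields fewer informative components (explained variance 0).
    """
    if species is None:
        species = [c for c in solutions.columns if c not in ("replicate", "model")]
    X = np.log10(solutions[list(species)].to_numpy() + 1e-12)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 3 solutions and >= 2 species")
    sd = X.std(axis=0, ddof=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    k = min(n_components, Xs.shape[0], Xs.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(Xs)
    return coords, pca.explained_variance_ratio_
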