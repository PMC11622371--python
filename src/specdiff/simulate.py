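"""Artificial mass-spectrum process simulation and the PCA/PLS-DA benchmark.

The simulator emulates integrated ToF-SIMS-like peak tables: on the order
of a thousand peaks with count intensities spanning orders of magnitude
and Poisson counting noise. A *process mechanism* modifies a random half
of the peaks — each selected peak increases or decreases with equal
probability at a peak-specific rate — and a dimensionless, time-like
extent parameter ``t`` controls how far the process has run. Datasets
pair three "initial" spectra with three "artificial" spectra drawn as
independent Poisson realizations of the mean processed spectrum, so the
two classes share no one-to-one noise correlations.

Update rules (selected peak with initial intensity p0, rate r, factor F):

    decrease:  p(t) = p0 * exp(-r t)
    increase:  p(t) = p0 * (1 + F * (1 - exp(-r t)))
    unselected peaks are unchanged.

Both rules are the identity at t = 0, monotone in t, and keep intensities
nonnegative and bounded; the factor F acts only on increases. They are
isolated behind :func:`apply_mechanism` so alternative kinetics can be
swapped in.

The Monte-Carlo benchmark measures how reliably PCA and PLS-DA recover a
known mechanism direction: many replicate datasets, each from a freshly
sampled mechanism, are fit with both methods; the discriminating
component is selected by the between-within score ratio, sign-aligned to
the reference, and scored by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decompose import angle_deg, cosine_similarity, gram_schmidt, planarity_residual
from .loading import LoadingVector
from .mva import (
    align_sign,
    fit_pca,
    fit_plsda,
    plsda_permutation_pvalue,
)
from .peaktable import PeakList, SpectrumSet
from .preprocess import preprocess

__all__ = [
    "MechanismParams",
    "MechanismSpec",
    "SimulationConfig",
    "BenchmarkResult",
    "TwoMechanismStudy",
    "FAST_MECHANISM",
    "SLOW_MECHANISM",
    "sample_mechanism",
    "apply_mechanism",
    "mechanism_delta",
    "chain_deltas",
    "make_initial_spectra",
    "make_dataset",
    "fit_dataset_loadings",
    "run_benchmark",
    "run_two_mechanism_study",
    "null_separation_pvalues",
]

INITIAL_LABEL = "initial"
ARTIFICIAL_LABEL = "artificial"


@dataclass(frozen=True)
class MechanismParams:
    """Distribution parameters of one mechanism.

    Update rates are drawn from Normal(mu, sigma) (clipped at 0 so the
    update rules stay monotone in t); update factors for increasing peaks
    from Uniform(f_lo, f_hi).
    """

    mu: float
    sigma: float
    f_lo: float = 1.0
    f_hi: float = 5.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not (0 <= self.f_lo <= self.f_hi):
            raise ValueError("require 0 <= f_lo <= f_hi")


#: default fast mechanism (#1) — roughly 5x the slow mechanism's rate
FAST_MECHANISM = MechanismParams(mu=1.0, sigma=0.25)
#: default slow mechanism (#2)
SLOW_MECHANISM = MechanismParams(mu=0.2, sigma=0.05)


@dataclass(frozen=True)
class MechanismSpec:
    """The sampled randomness defining one artificial process mechanism."""

    selected: np.ndarray        # column indices of modified peaks
    direction: np.ndarray       # +1 (increase) / -1 (decrease), per selected
    rate: np.ndarray            # r_i per selected peak
    factor: np.ndarray          # F_i per selected peak; NaN where decreasing
    params: MechanismParams
    seed: int | None = None

    def __post_init__(self):
        n = self.selected.size
        if self.direction.size != n or self.rate.size != n or self.factor.size != n:
            raise ValueError("per-peak arrays must align with selected peaks")
        inc = self.direction > 0
        if np.any(~np.isfinite(self.factor[inc])):
            raise ValueError("every increasing peak needs an update factor")


def sample_mechanism(peaks: PeakList | int, params: MechanismParams,
                     rng) -> MechanismSpec:
    """Sample one mechanism: half the peaks, fair directions, rates, factors.

    Fully reproducible from the generator state; exactly ``floor(n/2)``
    peaks are selected uniformly without replacement.
    """
    rng = np.random.default_rng(rng)
    n = peaks if isinstance(peaks, int) else len(peaks)
    if n < 2:
        raise ValueError("need at least 2 peaks to sample a mechanism")
    n_sel = n // 2
    selected = np.sort(rng.choice(n, size=n_sel, replace=False))
    direction = rng.choice([-1, 1], size=n_sel)
    rate = np.clip(rng.normal(params.mu, params.sigma, size=n_sel), 0.0, None)
    factor = np.full(n_sel, np.nan)
    inc = direction > 0
    factor[inc] = rng.uniform(params.f_lo, params.f_hi, size=int(inc.sum()))
    return MechanismSpec(selected, direction, rate, factor, params)


def apply_mechanism(intensities: np.ndarray, spec: MechanismSpec,
                    t: float) -> np.ndarray:
    """Apply one mechanism's update rules at process time ``t``.

    Operates on a spectra-by-peaks matrix; unselected peaks pass through
    unchanged and ``t = 0`` is the identity.
    """
    if t < 0:
        raise ValueError("process time t must be nonnegative")
    X = np.asarray(intensities, dtype=float)
    if spec.selected.size and spec.selected.max() >= X.shape[1]:
        raise ValueError("mechanism indexes peaks beyond the matrix width")
    out = X.copy()
    decay = np.exp(-spec.rate * t)
    dec = spec.direction < 0
    inc = ~dec
    cols_dec = spec.selected[dec]
    cols_inc = spec.selected[inc]
    out[:, cols_dec] = X[:, cols_dec] * decay[dec]
    out[:, cols_inc] = X[:, cols_inc] * (1.0 + spec.factor[inc] * (1.0 - decay[inc]))
    return np.clip(out, 0.0, None)


def mechanism_delta(initial, spec: MechanismSpec, t: float,
                    baseline: np.ndarray | None = None) -> np.ndarray:
    """Per-peak mean intensity change caused by one mechanism at time ``t``.

    ``baseline`` is the matrix the mechanism acts on at its stage in the
    chain (defaults to the initial intensities); the delta is the mean
    over spectra of (after - before). Unselected peaks have exactly zero
    entries. This is the ground-truth direction each mechanism imprints
    on the spectra, available because mechanism contributions are
    computed before they are combined.
    """
    if baseline is None:
        baseline = initial.intensities if isinstance(initial, SpectrumSet) else initial
    baseline = np.asarray(baseline, dtype=float)
    return (apply_mechanism(baseline, spec, t) - baseline).mean(axis=0)


def chain_deltas(initial, specs: Sequence[MechanismSpec],
                 t: float) -> list[np.ndarray]:
    """Per-mechanism deltas when mechanisms are applied sequentially."""
    X = initial.intensities if isinstance(initial, SpectrumSet) else initial
    X = np.asarray(X, dtype=float)
    deltas = []
    for spec in specs:
        nxt = apply_mechanism(X, spec, t)
        deltas.append((nxt - X).mean(axis=0))
        X = nxt
    return deltas


#: replicate-to-replicate relative intensity variability of measured spectra
DEFAULT_REPLICATE_CV = 0.03


def make_initial_spectra(n_peaks: int = 993, n_spectra: int = 3,
                         intensity_decades: tuple[float, float] = (2.0, 6.0),
                         mz_range: tuple[float, float] = (1.0, 3661.0),
                         replicate_cv: float = DEFAULT_REPLICATE_CV,
                         rng=None) -> SpectrumSet:
    """Synthesize replicate initial spectra with ToF-SIMS-like statistics.

    Peak base intensities are log-uniform across ``intensity_decades``
    (default 1e2 to 1e6 counts). Each replicate spectrum is an
    independent Poisson realization of the base spectrum modulated by a
    per-peak multiplicative log-normal factor with coefficient of
    variation ``replicate_cv``: replicate spectra of a real surface are
    reproducible to a few percent at best, which far exceeds Poisson
    counting noise for high-count peaks, so Poisson resampling alone
    would make the initial class unrealistically homogeneous. Center
    masses are sorted uniform draws over ``mz_range``.
    """
    rng = np.random.default_rng(rng)
    mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    base = 10.0 ** rng.uniform(*intensity_decades, size=n_peaks)
    expected = base * np.exp(
        rng.normal(0.0, replicate_cv, size=(n_spectra, n_peaks)))
    counts = rng.poisson(expected).astype(float)
    return SpectrumSet(
        peaks=PeakList(mz),
        intensities=counts,
        labels=(INITIAL_LABEL,) * n_spectra,
        meta={"synthetic": True, "base_decades": intensity_decades,
              "replicate_cv": replicate_cv},
    )


def make_dataset(initial: SpectrumSet, mechanisms: Sequence[MechanismSpec],
                 t: float, rng, n_replicate_spectra: int = 3) -> SpectrumSet:
    """Build a two-class dataset: initial spectra vs processed spectra.

    Every mechanism is applied in order to every initial spectrum; the
    mean processed spectrum is computed and ``n_replicate_spectra``
    independent Poisson realizations of it form the "artificial" class,
    removing one-to-one noise correlations with the originals.
    """
    if initial.n_spectra < 2:
        raise ValueError("need at least 2 initial spectra")
    rng = np.random.default_rng(rng)
    X = initial.intensities
    for spec in mechanisms:
        X = apply_mechanism(X, spec, t)
    mean_spectrum = X.mean(axis=0)
    artificial = rng.poisson(mean_spectrum,
                             size=(n_replicate_spectra, initial.n_peaks))
    labels = (tuple(initial.labels or (INITIAL_LABEL,) * initial.n_spectra)
              + (ARTIFICIAL_LABEL,) * n_replicate_spectra)
    return SpectrumSet(
        peaks=initial.peaks,
        intensities=np.vstack([initial.intensities, artificial.astype(float)]),
        labels=labels,
        meta={**initial.meta, "t": t, "n_mechanisms": len(mechanisms)},
    )


def fit_dataset_loadings(dataset: SpectrumSet):
    """Preprocess a two-class dataset and fit both MVA methods.

    Returns ``(pca_loading, plsda_loading)`` — the back-transformed unit
    loading of the discriminating component of each method, selected by
    the between-within score ratio.
    """
    centered, state = preprocess(dataset)
    labels = dataset.labels
    pca = fit_pca(centered, state, labels=labels)
    plsda = fit_plsda(centered, labels, state)
    return pca.selected_loading, plsda.selected_loading


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a Monte-Carlo loading-recovery benchmark.

    ``mechanisms`` holds one (single-process study) or two (fast #1 then
    slow #2) parameter sets; with two, #1 must be faster (larger mu).
    The reference direction is the PLS-DA loading of a mechanism-#1-only
    dataset at ``t_ref`` ("empirical", the default) or the analytic
    mechanism delta ("analytic").
    """

    t_values: tuple = (0.03, 0.06, 0.1, 1.0)
    n_datasets: int = 1000
    mechanisms: tuple = (FAST_MECHANISM,)
    n_peaks: int = 993
    n_initial_spectra: int = 3
    n_replicate_spectra: int = 3
    intensity_decades: tuple = (2.0, 6.0)
    replicate_cv: float = DEFAULT_REPLICATE_CV
    t_ref: float = 1.0
    reference: str = "empirical"
    master_seed: int = 0

    def __post_init__(self):
        if any(t < 0 for t in self.t_values):
            raise ValueError("t_values must be nonnegative")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not 1 <= len(self.mechanisms) <= 2:
            raise ValueError("1 or 2 mechanisms supported")
        if len(self.mechanisms) == 2 and not (
                self.mechanisms[0].mu > self.mechanisms[1].mu):
            raise ValueError("mechanism #1 must be faster (larger mu) than #2")
        if self.reference not in ("empirical", "analytic"):
            raise ValueError("reference must be 'empirical' or 'analytic'")


def _dataset_rngs(master_seed: int, i: int, n_streams: int):
    """Independent generators for dataset ``i``, derived in counter mode."""
    children = np.random.SeedSequence(entropy=master_seed,
                                      spawn_key=(i,)).spawn(n_streams)
    return [np.random.default_rng(s) for s in children]


def _reference_direction(config: SimulationConfig, initial: SpectrumSet,
                         mech1: MechanismSpec, rng) -> LoadingVector:
    if config.reference == "analytic":
        delta = mechanism_delta(initial, mech1, config.t_ref)
        return LoadingVector(delta, peaks=initial.peaks,
                             provenance={"reference": "analytic-delta"})
    ref_set = make_dataset(initial, [mech1], config.t_ref, rng,
                           config.n_replicate_spectra)
    _, plsda = fit_dataset_loadings(ref_set)
    return plsda


@dataclass
class BenchmarkResult:
    """Per (method, t) cosine similarities to the target direction.

    Similarities are recorded after sign alignment, so each lies in
    [0, 1]; the summary angle is ``arccos`` of the mean similarity.
    """

    similarities: dict
    target: str
    config: SimulationConfig
    n_failed: int = 0

    def mean_similarity(self, method: str, t: float) -> float:
        return float(np.mean(self.similarities[(method, t)]))

    def angle(self, method: str, t: float) -> float:
        return angle_deg(self.mean_similarity(method, t))


def run_benchmark(config: SimulationConfig,
                  initial: SpectrumSet | None = None) -> BenchmarkResult:
    """Monte-Carlo comparison of PCA and PLS-DA loading recovery.

    For each replicate a distinct random process is sampled: fresh
    mechanism(s) (and fresh synthetic initial spectra unless ``initial``
    is supplied), a reference direction from a mechanism-#1-only dataset
    at ``t_ref``, and one dataset per ``t`` on which both methods are fit.
    Selected loadings are sign-aligned to the reference and scored by
    cosine similarity; keys ``("pca", t)`` and ``("plsda", t)`` score
    against the reference, ``("pca_vs_plsda", t)`` scores the two methods
    against each other. Datasets that fail to fit are counted and
    skipped, never silently dropped.
    """
    sims: dict = {(m, t): [] for t in config.t_values
                  for m in ("pca", "plsda", "pca_vs_plsda")}
    n_failed = 0
    for i in range(config.n_datasets):
        rng_init, rng_mech, rng_ref, rng_data = _dataset_rngs(
            config.master_seed, i, 4)
        init = initial if initial is not None else make_initial_spectra(
            config.n_peaks, config.n_initial_spectra,
            config.intensity_decades, replicate_cv=config.replicate_cv,
            rng=rng_init)
        mechs = [sample_mechanism(init.peaks, p, rng_mech)
                 for p in config.mechanisms]
        try:
            ref = _reference_direction(config, init, mechs[0], rng_ref)
            for t in config.t_values:
                dataset = make_dataset(init, mechs, t, rng_data,
                                       config.n_replicate_spectra)
                pca_l, plsda_l = fit_dataset_loadings(dataset)
                pca_l = align_sign(pca_l, ref)
                plsda_l = align_sign(plsda_l, ref)
                sims[("pca", t)].append(abs(cosine_similarity(pca_l, ref)))
                sims[("plsda", t)].append(abs(cosine_similarity(plsda_l, ref)))
                sims[("pca_vs_plsda", t)].append(
                    abs(cosine_similarity(pca_l, plsda_l)))
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
    return BenchmarkResult(
        similarities={k: np.asarray(v) for k, v in sims.items()},
        target=f"{config.reference} mechanism-#1 direction at t={config.t_ref}",
        config=config, n_failed=n_failed,
    )


@dataclass
class TwoMechanismStudy:
    """Per-dataset geometry of two-mechanism processes.

    For every replicate and every long time ``t_L``: the similarity of
    the long-time loading to the mechanism-#1 reference, the coplanarity
    residual of (reference, short-time loading, long-time loading), and
    the absolute cosines of the Gram-Schmidt parallel/orthogonal
    components of L(t_L) (projected onto L(t_S)) with each mechanism's
    ground-truth intensity-change direction.
    """

    t_short: float
    t_long_values: tuple
    sim_ref_long: dict       # t_L -> array of |cos(ref, L(t_L))|
    residual: dict           # t_L -> array of planarity residuals (deg)
    parallel_sim: dict       # t_L -> (n, 2) array: |cos(P, delta_mech)| per mech
    orthogonal_sim: dict     # t_L -> (n, 2) array: |cos(O, delta_mech)| per mech
    n_failed: int = 0

    def mean_angle_to_ref(self, t_long: float) -> float:
        return angle_deg(float(np.mean(self.sim_ref_long[t_long])))


def run_two_mechanism_study(n_datasets: int = 100, t_short: float = 0.1,
                            t_long_values: Sequence[float] = (0.5, 1.0, 5.0),
                            config: SimulationConfig | None = None,
                            master_seed: int = 0) -> TwoMechanismStudy:
    """Replicate the two-mechanism loading geometry over many processes.

    Each replicate samples a fast mechanism #1 and slow mechanism #2,
    fits the mechanism-#1 reference (PLS-DA at t=1, mechanism #1 only),
    the short-time loading L(t_S), and one long-time loading L(t_L) per
    requested value, then records angles, coplanarity residuals, and the
    similarity of the Gram-Schmidt components of L(t_L) onto L(t_S) with
    each mechanism's analytic delta at t_L.
    """
    if config is None:
        config = SimulationConfig(
            mechanisms=(FAST_MECHANISM, SLOW_MECHANISM),
            n_datasets=n_datasets, master_seed=master_seed,
            t_values=(t_short, *t_long_values),
        )
    t_long_values = tuple(t_long_values)
    sim_ref_long = {t: [] for t in t_long_values}
    residual = {t: [] for t in t_long_values}
    par_sim = {t: [] for t in t_long_values}
    orth_sim = {t: [] for t in t_long_values}
    n_failed = 0
    for i in range(n_datasets):
        rng_init, rng_mech, rng_ref, rng_data = _dataset_rngs(
            config.master_seed, i, 4)
        init = make_initial_spectra(config.n_peaks, config.n_initial_spectra,
                                    config.intensity_decades,
                                    replicate_cv=config.replicate_cv,
                                    rng=rng_init)
        mechs = [sample_mechanism(init.peaks, p, rng_mech)
                 for p in config.mechanisms]
        try:
            ref = _reference_direction(config, init, mechs[0], rng_ref)
            short_set = make_dataset(init, mechs, t_short, rng_data,
                                     config.n_replicate_spectra)
            _, l_short = fit_dataset_loadings(short_set)
            l_short = align_sign(l_short, ref)
            for t_long in t_long_values:
                long_set = make_dataset(init, mechs, t_long, rng_data,
                                        config.n_replicate_spectra)
                _, l_long = fit_dataset_loadings(long_set)
                l_long = align_sign(l_long, ref)
                sim_ref_long[t_long].append(
                    abs(cosine_similarity(ref, l_long)))
                residual[t_long].append(
                    planarity_residual(ref, l_short, l_long))
                decomp = gram_schmidt(l_long, l_short)
                d1, d2 = chain_deltas(init, mechs, t_long)
                par_sim[t_long].append([
                    abs(cosine_similarity(decomp.parallel, d1)),
                    abs(cosine_similarity(decomp.parallel, d2))])
                orth_sim[t_long].append([
                    abs(cosine_similarity(decomp.orthogonal, d1)),
                    abs(cosine_similarity(decomp.orthogonal, d2))])
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
    return TwoMechanismStudy(
        t_short=t_short, t_long_values=t_long_values,
        sim_ref_long={t: np.asarray(v) for t, v in sim_ref_long.items()},
        residual={t: np.asarray(v) for t, v in residual.items()},
        parallel_sim={t: np.asarray(v) for t, v in par_sim.items()},
        orthogonal_sim={t: np.asarray(v) for t, v in orth_sim.items()},
        n_failed=n_failed,
    )


def null_separation_pvalues(n_replicates: int = 50, n_permutations: int = 100,
                            n_peaks: int = 993, master_seed: int = 0) -> np.ndarray:
    """Permutation p-values for PLS-DA separation on no-change datasets.

    At ``t = 0`` the artificial class is just a Poisson re-draw of the
    initial mean spectrum, so class separation should be statistically
    indistinguishable from the label-shuffle null.
    """
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        rng_init, rng_mech, rng_data, rng_perm = _dataset_rngs(
            master_seed, i, 4)
        init = make_initial_spectra(n_peaks, rng=rng_init)
        mech = sample_mechanism(init.peaks, FAST_MECHANISM, rng_mech)
        dataset = make_dataset(init, [mech], 0.0, rng_data)
        centered, state = preprocess(dataset)
        pvals[i] = plsda_permutation_pvalue(
            centered, dataset.labels, state,
            n_permutations=n_permutations, rng=rng_perm)
    return pvals
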