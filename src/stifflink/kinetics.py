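"""Two-state kinetics from constant-trap-distance traces.

Two complementary routes to the folding/unfolding rate constants of a
hairpin hopping in equilibrium:

* threshold (Schmitt-trigger) state assignment followed by dwell-time
  maximum likelihood, ``k = 1/<dwell>`` per state, and
* a two-state Gaussian-emission hidden-Markov fit, with rates taken from
  the transition matrix in the small-probability limit ``k_ij = a_ij f_s``
  (for per-sample transition probabilities a < 0.02 this differs from
  ``-f_s ln(1 - a)`` by under 1 %).

States follow the package convention 0 = folded, 1 = unfolded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .io import Trace

__all__ = [
    "StateSequence",
    "RateEstimate",
    "HmmFit",
    "assign_states_threshold",
    "dwell_rates",
    "fit_hmm_two_state",
    "force_dependent_rates",
]


class KineticsError(RuntimeError):
    """Raised when rates cannot be estimated from a trace."""


@dataclass
class StateSequence:
    states: np.ndarray  # int8, 0=folded, 1=unfolded
    sample_rate: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class RateEstimate:
    k_unfold: float  # 1/s, rate out of the folded state
    k_fold: float  # 1/s, rate out of the unfolded state
    se_unfold: float
    se_fold: float
    n_dwells: int
    mean_force_folded: float = np.nan
    mean_force_unfolded: float = np.nan


@dataclass
class HmmFit:
    means: np.ndarray  # (2,) emission means, ordered [folded, unfolded]
    sds: np.ndarray  # (2,) emission SDs
    transmat: np.ndarray  # (2,2) per-sample transition probabilities
    log_likelihood: float
    path: StateSequence | None
    converged: bool
    sample_rate: float

    @property
    def k_unfold(self) -> float:
        if not self.converged:
            raise KineticsError("HMM did not converge; rates undefined")
        return float(self.transmat[0, 1] * self.sample_rate)

    @property
    def k_fold(self) -> float:
        if not self.converged:
            raise KineticsError("HMM did not converge; rates undefined")
        return float(self.transmat[1, 0] * self.sample_rate)


def assign_states_threshold(signal: np.ndarray, midpoint: float,
                            hysteresis: float,
                            sample_rate: float = 2e4) -> StateSequence:
    """Schmitt-trigger state assignment with a hysteresis band.

    The state flips to 1 only when the signal exceeds
    ``midpoint + hysteresis/2`` and back to 0 only below
    ``midpoint - hysteresis/2``; inside the band the previous state is kept.
    Samples before the first threshold crossing take the state implied by
    the nearer threshold.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    hi = midpoint + hysteresis / 2.0
    lo = midpoint - hysteresis / 2.0
    n = len(signal)
    # decided samples: above hi -> 1, below lo -> 0; in-band samples inherit
    # the last decided state (vectorized forward fill)
    decided = np.full(n, -1, dtype=np.int8)
    decided[signal > hi] = 1
    decided[signal < lo] = 0
    idx = np.where(decided >= 0, np.arange(n), -1)
    np.maximum.accumulate(idx, out=idx)
    init = 1 if signal[0] >= midpoint else 0
    states = np.where(idx >= 0, decided[np.maximum(idx, 0)], init).astype(np.int8)
    return StateSequence(states=states, sample_rate=sample_rate)


def _dwell_times(states: np.ndarray, sample_rate: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Complete (uncensored) dwell times per state, seconds."""
    change = np.flatnonzero(np.diff(states) != 0)
    if change.size < 2:
        return np.empty(0), np.empty(0)
    # runs strictly between the first and last transition are complete
    starts = change[:-1] + 1
    ends = change[1:] + 1
    lengths = (ends - starts) / sample_rate
    run_states = states[starts]
    return lengths[run_states == 0], lengths[run_states == 1]


def dwell_rates(states: StateSequence, force: np.ndarray | None = None
                ) -> RateEstimate:
    """Maximum-likelihood dwell-time rates: k = 1/mean(complete dwells).

    The censored first and last dwells are excluded.  Standard errors are
    ``k/sqrt(n)`` (exact for exponential dwell MLE).  Raises
    :class:`KineticsError` when fewer than two transitions are present
    (rate undefined).
    """
    d0, d1 = _dwell_times(states.states, states.sample_rate)
    if d0.size == 0 and d1.size == 0:
        raise KineticsError("rate undefined: fewer than 2 transitions")
    if d0.size == 0 or d1.size == 0:
        raise KineticsError("rate undefined: no complete dwell in one state")
    k_unfold = 1.0 / d0.mean()
    k_fold = 1.0 / d1.mean()
    mff = mfu = np.nan
    if force is not None:
        force = np.asarray(force, dtype=float)
        mff = float(force[states.states == 0].mean())
        mfu = float(force[states.states == 1].mean())
    return RateEstimate(
        k_unfold=k_unfold,
        k_fold=k_fold,
        se_unfold=k_unfold / np.sqrt(d0.size),
        se_fold=k_fold / np.sqrt(d1.size),
        n_dwells=int(d0.size + d1.size),
        mean_force_folded=mff,
        mean_force_unfolded=mfu,
    )


def fit_hmm_two_state(signal: np.ndarray, sample_rate: float,
                      max_iter: int = 500, tol: float = 1e-6,
                      seed: int = 0) -> HmmFit:
    """Two-state Gaussian-emission HMM fitted by expectation-maximization.

    Initialization splits the signal at its median (2-quantile split);
    ``tol`` is the relative log-likelihood change declaring convergence.
    The fit is flagged unconverged when EM stalls or when the fitted means
    are closer than the pooled emission SD (one noisy population — the
    regime where floppy-linker data defeats the analysis).  States are
    ordered by mean: 0 = lower (folded), 1 = upper (unfolded).
    """
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    if len(signal) < 1000:
        raise ValueError("signal too short for HMM fitting (need >= 1000)")
    # 2-quantile split; the cut sits between the quartiles so a discrete
    # two-level signal (median equal to one level) still splits both ways
    q25, q75 = np.quantile(signal, [0.25, 0.75])
    cut = 0.5 * (q25 + q75)
    lower, upper = signal[signal <= cut], signal[signal > cut]
    if lower.size == 0 or upper.size == 0:
        sd = max(signal.std(), 1e-6)
        lower = np.array([signal.mean() - sd])
        upper = np.array([signal.mean() + sd])
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol * len(signal),  # hmmlearn tol is absolute; total loglik ~ N
        init_params="",
        params="stmc",
        random_state=seed,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    model.means_ = np.array([[lower.mean()], [upper.mean()]])
    var0 = max(lower.var(), 1e-12)
    var1 = max(upper.var(), 1e-12)
    model.covars_ = np.array([[var0], [var1]])
    X = signal.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X)
    em_converged = bool(model.monitor_.converged)
    means = model.means_.ravel()
    sds = np.sqrt(model.covars_.ravel())
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    transmat = model.transmat_[np.ix_(order, order)]
    pooled_sd = float(np.sqrt(np.mean(sds**2)))
    separated = abs(means[1] - means[0]) > pooled_sd
    converged = em_converged and separated
    path = None
    if separated:
        raw_path = model.predict(X)
        relabel = np.empty(2, dtype=np.int8)
        relabel[order] = [0, 1]
        path = StateSequence(states=relabel[raw_path], sample_rate=sample_rate)
    return HmmFit(
        means=means,
        sds=sds,
        transmat=transmat,
        log_likelihood=float(model.monitor_.history[-1]),
        path=path,
        converged=converged,
        sample_rate=sample_rate,
    )


def force_dependent_rates(
    traces: list[tuple[Trace, StateSequence]]
) -> pd.DataFrame:
    """Per-trace dwell rates and state-conditioned mean forces.

    Returns a DataFrame with columns force_folded_pN, force_unfolded_pN,
    k_unfold_per_s, k_fold_per_s, se_unfold, se_fold, n_dwells, sorted by
    the folded-state force.  Traces whose rates are undefined are skipped
    with a warning.
    """
    rows = []
    for i, (trace, states) in enumerate(traces):
        try:
            est = dwell_rates(states, force=trace.force)
        except KineticsError as err:
            warnings.warn(f"trace {i}: {err}; skipped")
            continue
        rows.append(
            {
                "force_folded_pN": est.mean_force_folded,
                "force_unfolded_pN": est.mean_force_unfolded,
                "k_unfold_per_s": est.k_unfold,
                "k_fold_per_s": est.k_fold,
                "se_unfold": est.se_unfold,
                "se_fold": est.se_fold,
                "n_dwells": est.n_dwells,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "force_folded_pN",
            "force_unfolded_pN",
            "k_unfold_per_s",
            "k_fold_per_s",
            "se_unfold",
            "se_fold",
            "n_dwells",
        ],
    )
    return df.sort_values("force_folded_pN", ignore_index=True) if len(df) else df
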