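"""Bayesian phase/sequence model of a collection unit, sampled by Gibbs MCMC.

A dated analysis unit is a *phase*: its dated events are i.i.d. uniform
between an unknown older boundary ``alpha`` and younger boundary ``beta``
(ages in cal BP, larger = older).  Given the boundaries the likelihood of the
``n`` events is ``(alpha - beta)^(-n)``; a configurable span-prior exponent
``e`` contributes ``(alpha - beta)^(+e)``, so the conditional for each
boundary is an analytic power law.  The default ``e = n - 1`` makes the
implied prior on the phase span uniform.  A *sequence* orders phases oldest
to youngest by constraining the younger boundary of each phase to be at
least the older boundary of the next.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .calibration import CalibratedDensity, CalibrationCurve, calendar_density, calibrate_radiocarbon
from .units import AnalysisUnit, CollectionUnit

__all__ = [
    "PhaseSpec",
    "SequenceSpec",
    "PosteriorSamples",
    "ConvergenceReport",
    "ModelBuildError",
    "InitializationError",
    "build_collection_model",
    "infer_order",
    "log_posterior_density",
    "sample_posterior",
    "convergence_diagnostics",
]

RHAT_THRESHOLD = 1.05


class ModelBuildError(ValueError):
    """Raised when a collection cannot yield a phase model (e.g. no dated units)."""


class InitializationError(RuntimeError):
    """Raised when no feasible starting state can be constructed."""


@dataclass
class PhaseSpec:
    """One dated analysis unit: its event densities plus a predictive slot."""

    analysis_unit_ref: str
    event_densities: List[CalibratedDensity]
    include_predictive: bool = True
    date_labels: List[Optional[str]] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.event_densities)


@dataclass
class SequenceSpec:
    """A collection-unit model: phases, optionally ordered oldest to youngest.

    ``order`` holds indices into ``phases`` (oldest first) when ``ordered``.
    """

    phases: List[PhaseSpec]
    ordered: bool = False
    order: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if self.ordered:
            if self.order is None or sorted(self.order) != list(range(len(self.phases))):
                raise ValueError("ordered sequence requires a permutation of phase indices")
        elif self.order is None:
            self.order = list(range(len(self.phases)))


@dataclass
class PosteriorSamples:
    """Kept MCMC draws, shaped ``(chains, n_kept)`` per monitored quantity.

    ``events[j]`` has shape ``(n_dates_j, chains, n_kept)``; ``predictive``,
    ``alpha`` and ``beta`` are lists over phases of ``(chains, n_kept)``
    arrays.  ``unit_ids[j]`` names the analysis unit behind phase ``j``.
    """

    unit_ids: List[str]
    events: List[np.ndarray]
    predictive: List[np.ndarray]
    alpha: List[np.ndarray]
    beta: List[np.ndarray]
    chains: int
    seed: int
    n_kept: int
    warnings: List[str] = field(default_factory=list)

    @property
    def n_phases(self) -> int:
        return len(self.unit_ids)

    def event_draws(self, j: int, i: int) -> np.ndarray:
        return self.events[j][i].ravel()

    def predictive_draws(self, j: int) -> np.ndarray:
        return self.predictive[j].ravel()

    def alpha_draws(self, j: int) -> np.ndarray:
        return self.alpha[j].ravel()

    def beta_draws(self, j: int) -> np.ndarray:
        return self.beta[j].ravel()


def infer_order(
    cu: CollectionUnit, unit_ids: Optional[Sequence[str]] = None
) -> Tuple[bool, List[str]]:
    """Decide whether the units have a clear stratigraphic order.

    Returns ``(ordered, ids_oldest_to_youngest)``.  Order comes from an
    explicit ``declared_order`` on the collection, or failing that from
    distinct numeric depths (deeper = older).  Ties or missing depths
    degrade to unordered with a warning.
    """
    if unit_ids is None:
        unit_ids = [au.id for au in cu.analysis_units if au.dates]
    unit_ids = list(unit_ids)

    if cu.declared_order is not None:
        declared = [uid for uid in cu.declared_order if uid in unit_ids]
        if set(declared) == set(unit_ids) and len(unit_ids) > 0:
            return True, declared
        _warnings.warn(
            f"collection {cu.id}: declared order does not cover all dated units; "
            "treating as unordered"
        )
        return False, unit_ids

    units = [cu.unit(uid) for uid in unit_ids]
    depths = [au.depth for au in units]
    if len(units) >= 2 and all(d is not None for d in depths):
        if len(set(depths)) == len(depths):
            ordered_ids = [au.id for au in sorted(units, key=lambda a: -a.depth)]
            return True, ordered_ids
        _warnings.warn(
            f"collection {cu.id}: duplicate depths cannot define a clear "
            "stratigraphic order; treating as unordered"
        )
    return False, unit_ids


def build_collection_model(cu: CollectionUnit, curve: CalibrationCurve) -> SequenceSpec:
    """Build a phase/sequence model from a collection's dated analysis units.

    Dates must already have passed :func:`paleochron.neotoma_io.filter_geochron_dates`;
    any remaining obviously-unusable dates (single-sided, zero error) are
    dropped defensively.  Undated units never enter the model.
    """
    phases: List[PhaseSpec] = []
    dated_ids: List[str] = []
    for au in cu.analysis_units:
        densities = []
        labels = []
        for d in au.dates:
            if d.single_sided or d.error_minus <= 0 or d.error_plus <= 0:
                continue
            if d.kind == "radiocarbon":
                densities.append(calibrate_radiocarbon(d, curve))
            else:
                densities.append(calendar_density(d, curve))
            labels.append(d.lab_id)
        if densities:
            phases.append(
                PhaseSpec(analysis_unit_ref=au.id, event_densities=densities, date_labels=labels)
            )
            dated_ids.append(au.id)

    if not phases:
        raise ModelBuildError(f"collection {cu.id} has no usable dated analysis units")

    ordered, order_ids = infer_order(cu, dated_ids)
    if ordered:
        index = {uid: j for j, uid in enumerate(dated_ids)}
        order = [index[uid] for uid in order_ids]
    else:
        order = None
    return SequenceSpec(phases=phases, ordered=ordered, order=order)


def _span_exponents(model: SequenceSpec, span_prior_exponent: Union[str, float]) -> List[float]:
    """Per-phase span-prior exponent e_j.

    ``"auto"`` -> n_j - 1 (uniform implied span prior), ``"flat"`` -> 0;
    numeric values are used as-is.  The joint density is integrable only for
    e_j - n_j > -(n_j + 1), i.e. e_j > -1; values at or below -1 make the
    posterior improper (span collapse) and are rejected.
    """
    if span_prior_exponent == "auto":
        exps = [float(ph.n_events - 1) for ph in model.phases]
    elif span_prior_exponent == "flat":
        exps = [0.0] * len(model.phases)
    else:
        exps = [float(span_prior_exponent)] * len(model.phases)
    for e in exps:
        if e <= -1.0:
            raise ValueError(
                f"span prior exponent {e} yields an improper posterior "
                "(requires exponent > -1)"
            )
    return exps


def log_posterior_density(
    model: SequenceSpec,
    state: List[Tuple[np.ndarray, float, float]],
    span_prior_exponent: Union[str, float] = "auto",
    overall_span_exponent: float = 0.0,
) -> float:
    """Log joint density (up to a constant) of a full state.

    ``state[j] = (t_j, alpha_j, beta_j)`` with ``t_j`` the event ages of
    phase ``j``.  Returns ``-inf`` whenever a containment, support or
    ordering constraint fails.  ``overall_span_exponent`` (kappa) adds a
    ``(max alpha - min beta)^(-kappa)`` coupling across phases.
    """
    if len(state) != len(model.phases):
        raise ValueError("state does not match model phase count")
    exps = _span_exponents(model, span_prior_exponent)
    logp = 0.0
    for j, (ph, (t, alpha, beta)) in enumerate(zip(model.phases, state)):
        t = np.asarray(t, dtype=float)
        if t.shape != (ph.n_events,):
            raise ValueError(f"phase {j}: expected {ph.n_events} event ages")
        grid = ph.event_densities[0].grid
        if not (grid[0] <= beta <= alpha <= grid[-1]):
            return -np.inf
        if (t < beta).any() or (t > alpha).any():
            return -np.inf
        span = alpha - beta
        for i, dens in enumerate(ph.event_densities):
            p = float(np.interp(t[i], dens.grid, dens.p))
            if p <= 0.0:
                return -np.inf
            logp += np.log(p)
        exponent = exps[j] - ph.n_events
        if span <= 0.0:
            if exponent < 0.0:
                return -np.inf
            if exponent > 0.0:
                return -np.inf  # zero span has zero density unless exponent == 0
        else:
            logp += exponent * np.log(span)
    if model.ordered:
        for a, b in zip(model.order[:-1], model.order[1:]):
            # younger boundary of the older phase must not undercut the
            # older boundary of the next (younger) phase
            if state[a][2] < state[b][1]:
                return -np.inf
    if overall_span_exponent != 0.0:
        total = max(s[1] for s in state) - min(s[2] for s in state)
        if total <= 0.0:
            return -np.inf
        logp -= overall_span_exponent * np.log(total)
    return logp


def _sample_truncated_power(
    rng: np.random.Generator, c: float, z0: float, z1: float
) -> float:
    """Draw z with density proportional to z**c on [z0, z1], 0 < z0 <= z1."""
    if z1 <= z0:
        return z0
    u = rng.uniform()
    if abs(c + 1.0) < 1e-12:
        return z0 * (z1 / z0) ** u
    k = c + 1.0
    return (z0**k + u * (z1**k - z0**k)) ** (1.0 / k)


def _init_state(
    model: SequenceSpec, grid: np.ndarray, cdfs: List[List[np.ndarray]]
) -> List[List]:
    """Feasible start: events near their medians, boundaries hugging them.

    For ordered models phases are processed oldest to youngest under a
    running cap; events are pushed to the youngest admissible cells when the
    cap binds.  Raises :class:`InitializationError` when the supports cannot
    satisfy the ordering.
    """
    h = float(grid[1] - grid[0])
    n_ph = len(model.phases)
    state: List[Optional[List]] = [None] * n_ph
    seq = model.order if model.ordered else list(range(n_ph))
    upper = float(grid[-1])
    for j in seq:
        ph = model.phases[j]
        t = np.empty(ph.n_events)
        for i, cdf in enumerate(cdfs[j]):
            hi_idx = int(np.searchsorted(grid, upper, side="right")) - 1
            if hi_idx < 0 or cdf[hi_idx] <= 1e-12:
                raise InitializationError(
                    f"phase {ph.analysis_unit_ref}: no density mass below the ordering cap"
                )
            idx = int(np.searchsorted(cdf, 0.5 * cdf[hi_idx]))
            idx = min(idx, hi_idx)
            t[i] = grid[idx]
        alpha = min(float(t.max()) + h, upper)
        beta = max(float(t.min()) - h, float(grid[0]))
        if alpha < t.max() or beta > t.min():
            raise InitializationError("could not fit boundaries around initial events")
        state[j] = [t, alpha, beta]
        if model.ordered:
            upper = beta
            if upper <= grid[0]:
                raise InitializationError("ordering cap collapsed to the grid floor")
    return [s for s in state]  # type: ignore[return-value]


def sample_posterior(
    model: SequenceSpec,
    n_iter: int = 25_000,
    burn_in: int = 5_000,
    thin: int = 5,
    chains: int = 2,
    seed: int = 0,
    span_prior_exponent: Union[str, float] = "auto",
    overall_span_exponent: float = 0.0,
) -> PosteriorSamples:
    """Gibbs-sample the phase model.

    Events are drawn by inverse CDF from their calibrated density restricted
    to the current boundaries; boundaries from their analytic truncated
    power-law conditionals; the predictive ("new event") age uniformly
    within the boundaries at every kept iteration.  A non-zero
    ``overall_span_exponent`` (kappa) couples the phases through a
    ``(max alpha - min beta)^(-kappa)`` factor, applied as a
    Metropolis-Hastings correction on the boundary updates.  Fully
    deterministic given ``seed``.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if chains < 2:
        raise ValueError("at least two chains are required")
    if seed is None:
        raise ValueError("a seed must be supplied")

    phases = model.phases
    n_ph = len(phases)
    grid = phases[0].event_densities[0].grid.astype(float)
    h = float(grid[1] - grid[0])
    g_lo, g_hi = float(grid[0]), float(grid[-1])
    exps = _span_exponents(model, span_prior_exponent)
    cs = [exps[j] - phases[j].n_events for j in range(n_ph)]  # boundary power-law exponent
    cdfs = [[np.cumsum(d.p) for d in ph.event_densities] for ph in phases]

    seq = model.order if model.ordered else list(range(n_ph))
    pos_in_seq = {j: k for k, j in enumerate(seq)}

    n_kept = (n_iter - burn_in) // thin
    events_out = [np.empty((ph.n_events, chains, n_kept)) for ph in phases]
    pred_out = [np.empty((chains, n_kept)) for _ in phases]
    alpha_out = [np.empty((chains, n_kept)) for _ in phases]
    beta_out = [np.empty((chains, n_kept)) for _ in phases]

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    for ch in range(chains):
        rng = np.random.default_rng(chain_seeds[ch])
        state = _init_state(model, grid, cdfs)
        kept = 0
        for it in range(n_iter):
            for k, j in enumerate(seq):
                t, alpha, beta = state[j]
                # --- events: inverse CDF restricted to [beta, alpha]
                i0 = int(np.searchsorted(grid, beta, side="left"))
                i1 = int(np.searchsorted(grid, alpha, side="right")) - 1
                for i, cdf in enumerate(cdfs[j]):
                    lo = cdf[i0 - 1] if i0 > 0 else 0.0
                    hi = cdf[i1]
                    u = rng.uniform(lo, hi)
                    idx = int(np.searchsorted(cdf, u, side="left"))
                    idx = min(max(idx, i0), i1)
                    t[i] = grid[idx]
                t_min = float(t.min())
                t_max = float(t.max())
                c = cs[j]
                kappa = overall_span_exponent
                if kappa != 0.0 and n_ph > 1:
                    others_max_a = max(state[jj][1] for jj in range(n_ph) if jj != j)
                    others_min_b = min(state[jj][2] for jj in range(n_ph) if jj != j)
                else:
                    others_max_a, others_min_b = -np.inf, np.inf
                # --- older boundary alpha
                cap = g_hi
                if model.ordered and k > 0:
                    cap = min(cap, state[seq[k - 1]][2])  # beta of next older phase
                z0 = max(t_max - beta, 1e-9)
                z1 = max(cap - beta, z0)
                prop = beta + _sample_truncated_power(rng, c, z0, z1)
                prop = min(max(prop, t_max), cap)
                if kappa != 0.0:
                    gmin_b = min(beta, others_min_b)
                    t_new = max(prop, others_max_a) - gmin_b
                    t_old = max(alpha, others_max_a) - gmin_b
                    if t_new <= t_old or rng.uniform() < (t_old / t_new) ** kappa:
                        alpha = prop
                else:
                    alpha = prop
                # --- younger boundary beta
                floor = g_lo
                if model.ordered and k + 1 < len(seq):
                    floor = max(floor, state[seq[k + 1]][1])  # alpha of next younger phase
                z0 = max(alpha - t_min, 1e-9)
                z1 = max(alpha - floor, z0)
                prop = alpha - _sample_truncated_power(rng, c, z0, z1)
                prop = max(min(prop, t_min), floor)
                if kappa != 0.0:
                    gmax_a = max(alpha, others_max_a)
                    t_new = gmax_a - min(prop, others_min_b)
                    t_old = gmax_a - min(beta, others_min_b)
                    if t_new <= t_old or rng.uniform() < (t_old / t_new) ** kappa:
                        beta = prop
                else:
                    beta = prop
                state[j] = [t, alpha, beta]
            if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_kept:
                for j in range(n_ph):
                    t, alpha, beta = state[j]
                    events_out[j][:, ch, kept] = t
                    alpha_out[j][ch, kept] = alpha
                    beta_out[j][ch, kept] = beta
                    pred_out[j][ch, kept] = rng.uniform(beta, alpha)
                kept += 1

    samples = PosteriorSamples(
        unit_ids=[ph.analysis_unit_ref for ph in phases],
        events=events_out,
        predictive=pred_out,
        alpha=alpha_out,
        beta=beta_out,
        chains=chains,
        seed=seed,
        n_kept=n_kept,
    )
    report = convergence_diagnostics(samples)
    if report.flagged:
        worst = max(report.rhat.items(), key=lambda kv: kv[1])
        msg = f"convergence warning: split R-hat {worst[1]:.3f} for {worst[0]} exceeds {RHAT_THRESHOLD}"
        _warnings.warn(msg)
        samples.warnings.append(msg)
    return samples


@dataclass
class ConvergenceReport:
    rhat: Dict[str, float]
    ess: Dict[str, float]
    flagged: bool


def _split_rhat(draws: np.ndarray) -> float:
    """Classic split-chain potential scale reduction for draws (chains, n)."""
    m, n = draws.shape
    half = n // 2
    if half < 2:
        return np.nan
    splits = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    nn = splits.shape[1]
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    W = variances.mean()
    B = nn * means.var(ddof=1)
    if W <= 0.0:
        return 1.0 if B <= 0.0 else np.inf
    var_plus = (nn - 1) / nn * W + B / nn
    return float(np.sqrt(var_plus / W))


def _ess(draws: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    m, n = draws.shape
    if n < 4:
        return float(m * n)
    acov = np.zeros(n)
    for ch in range(m):
        x = draws[ch] - draws[ch].mean()
        full = np.correlate(x, x, mode="full")[n - 1 :]
        acov += full / n
    acov /= m
    if acov[0] <= 0.0:
        return float(m * n)
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0.0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / max(tau, 1e-12))


def convergence_diagnostics(samples: PosteriorSamples) -> ConvergenceReport:
    """Split R-hat and effective sample size for every monitored quantity."""
    if samples.chains < 2:
        raise ValueError("diagnostics require at least two chains")
    rhat: Dict[str, float] = {}
    ess: Dict[str, float] = {}
    for j, uid in enumerate(samples.unit_ids):
        monitored = {
            f"alpha[{uid}]": samples.alpha[j],
            f"beta[{uid}]": samples.beta[j],
            f"predictive[{uid}]": samples.predictive[j],
        }
        for i in range(samples.events[j].shape[0]):
            monitored[f"t[{uid},{i}]"] = samples.events[j][i]
        for name, draws in monitored.items():
            rhat[name] = _split_rhat(np.asarray(draws))
            ess[name] = _ess(np.asarray(draws))
    flagged = any(np.isfinite(v) and v > RHAT_THRESHOLD or np.isinf(v) for v in rhat.values())
    return ConvergenceReport(rhat=rhat, ess=ess, flagged=flagged)
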