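"""Synthetic cohorts with the statistical structure the analysis assumes.

The generators emulate an incidental item-action encoding study: ~100
evaluation events answered yes/no by every participant (with a spectrum of
cross-participant agreement), a delayed three-question source-memory test,
and per-participant event-related node time series in which a designated set
of "hub" nodes synchronizes with the rest of the network during
deep-processing events.
Ground truth (hub identity, per-participant coupling gain, the gain-to-memory
slope) is returned alongside the data so that downstream recovery can be
tested.

All generators draw from a :class:`numpy.random.Generator` derived from an
explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .connectivity import HRFParams, canonical_hrf

__all__ = [
    "EventBank",
    "GroundTruth",
    "DesignSpec",
    "NodeTimeSeries",
    "RTModel",
    "MemoryEffects",
    "ITISpec",
    "NoiseSpec",
    "generate_event_bank",
    "generate_responses",
    "generate_memory_outcomes",
    "generate_design",
    "generate_node_timeseries",
    "sample_ground_truth",
]

# Mixture components for the population yes-rate of an item-question pairing.
# Chosen to reproduce the empirical agreement spectrum of the encoding task:
# near-unanimous "no" items (~99% no), near-unanimous "yes" items (~98% yes),
# and an ambiguous band whose yes-rates spread widely around 50%.
_NEAR0 = (1.3, 160.0)   # Beta: mean ~.008, SD ~.007
_NEAR1 = (160.0, 1.3)   # mirror image
_MID_LO, _MID_HI = 0.10, 0.90  # ambiguous component: 0.1 + 0.8*Beta(0.8, 0.8)
_MID_BETA = (0.8, 0.8)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class EventBank:
    """Population of encoding events (item-question pairings)."""

    event_id: np.ndarray        # int, 1..E, unique
    question: np.ndarray        # "eat" or "lift", balanced
    p_yes: np.ndarray           # population yes-rate per event, in [0, 1]

    def __post_init__(self) -> None:
        if len(self.event_id) < 8:
            raise ValueError("an event bank needs at least 8 events")
        if len(np.unique(self.event_id)) != len(self.event_id):
            raise ValueError("event ids must be unique")
        if np.any(self.p_yes < 0) or np.any(self.p_yes > 1):
            raise ValueError("p_yes must lie in [0, 1]")

    @property
    def n_events(self) -> int:
        return len(self.event_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"event_id": self.event_id, "question": self.question, "p_yes": self.p_yes}
        )


@dataclass
class GroundTruth:
    """Planted effect parameters linking coupling to memory ability.

    ``hub_nodes`` is the planted deep-processing network: during
    high-elaboration events those nodes synchronize with the network's
    common evoked signal, with strength set by the participant's
    ``coupling_gain``.  ``memory_slope`` links the gain to true
    source-memory ability, so that participants who centralize their hubs
    more strongly also remember more.
    """

    hub_nodes: np.ndarray           # node indices, subset of 0..n_nodes-1
    coupling_gain: np.ndarray       # per participant, >= 0
    memory_slope: float
    base_covariance: np.ndarray     # node x node, symmetric PSD
    #: loading with which optional affiliate nodes copy their hub's evoked
    #: amplitude during deep events, as a fraction of ``coupling_gain``
    spillover: float = 0.3
    #: nodes (disjoint from hubs) optionally recruited into the
    #: deep-processing interaction; empty (the default) means the planted
    #: effect is carried by hub-to-network common-mode coupling alone
    affiliates: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    #: hub index (into hub_nodes) each affiliate synchronizes with
    affiliate_hub: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        n = self.base_covariance.shape[0]
        if self.base_covariance.shape != (n, n):
            raise ValueError("base_covariance must be square")
        if not np.allclose(self.base_covariance, self.base_covariance.T):
            raise ValueError("base_covariance must be symmetric")
        if np.any(self.coupling_gain < 0):
            raise ValueError("coupling gains must be nonnegative")
        if np.any(self.hub_nodes < 0) or np.any(self.hub_nodes >= n):
            raise ValueError("hub nodes out of range")

    @property
    def n_nodes(self) -> int:
        return self.base_covariance.shape[0]


@dataclass
class DesignSpec:
    """Event-related design for one scanning run."""

    tr: float                       # seconds
    n_volumes: int
    onsets: np.ndarray              # seconds, strictly increasing
    durations: np.ndarray           # seconds
    condition_of_event: np.ndarray | None = None  # per-event labels

    def __post_init__(self) -> None:
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.onsets + self.durations > self.scan_length + 1e-9):
            raise ValueError("events extend past the end of the scan")

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    @property
    def scan_length(self) -> float:
        return self.n_volumes * self.tr


@dataclass
class NodeTimeSeries:
    """BOLD-like signal matrix for one participant/run: nodes x volumes."""

    participant_id: int
    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")


@dataclass
class RTModel:
    """Response-time model: ambiguous (mid yes-rate) events are slower."""

    base_ms: float = 848.0
    mid_shift_ms: float = 186.0
    sd_ms: float = 120.0
    mid_band: tuple[float, float] = (0.2, 0.8)
    floor_ms: float = 150.0


@dataclass
class MemoryEffects:
    """Logistic condition effects on the three-question test outcomes.

    Effects are on the log-odds of full source memory, with high/low coded
    +-1/2, so ``elab_effect=1.18`` yields condition rates near 64% vs 36%
    for the cohort-average participant.
    """

    elab_effect: float = 1.18
    congr_effect: float = 0.58
    ability_sd: float = 0.5
    base_logit: float = 0.0
    recognition_logit: float = 0.4   # extra recognition-only hits among non-source items
    q2_rate_nosource: float = 0.25   # "remember the action" claims without true source
    foil_fa_rate: float = 0.15


@dataclass
class ITISpec:
    """Inter-trial-interval model: 4 discrete values, exponential weights."""

    values: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    target_mean: float = 2.98


@dataclass
class NoiseSpec:
    """Observation noise for node time series."""

    ar1_rho: float = 0.3
    sigma: float = 0.5


def generate_event_bank(
    n_events: int = 100,
    agreement_profile: tuple[float, float, float] = (0.25, 0.25, 0.5),
    seed=None,
) -> EventBank:
    """Draw an event bank whose yes-rates follow a three-part mixture.

    ``agreement_profile`` gives weights over (near-0, near-1, mid) yes-rate
    components; the default puts half of the events in the ambiguous middle
    band so that the rank-based quartile classification later labels roughly
    the same events as high elaboration.
    """
    if n_events < 8:
        raise ValueError("n_events must be >= 8")
    w = np.asarray(agreement_profile, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("agreement_profile must be 3 nonnegative weights summing to 1")
    rng = _rng(seed)
    comp = rng.choice(3, size=n_events, p=w)
    p = np.empty(n_events)
    for c, (a, b) in enumerate((_NEAR0, _NEAR1)):
        m = comp == c
        p[m] = rng.beta(a, b, size=int(m.sum()))
    m = comp == 2
    p[m] = _MID_LO + (_MID_HI - _MID_LO) * rng.beta(*_MID_BETA, size=int(m.sum()))
    question = np.array(["eat", "lift"])[np.arange(n_events) % 2]
    rng.shuffle(question)
    return EventBank(event_id=np.arange(1, n_events + 1), question=question, p_yes=p)


def generate_responses(
    bank: EventBank,
    n_participants: int,
    rt_model: RTModel | None = None,
    seed=None,
) -> pd.DataFrame:
    """Simulate per-participant yes/no evaluations with response times.

    Responses are independent Bernoulli draws from each event's population
    yes-rate.  Mean RT is elevated by ``rt_model.mid_shift_ms`` for events in
    the ambiguous yes-rate band, mimicking the slower decisions observed for
    high-elaboration events.

    Returns a long table with columns
    ``participant_id, event_id, response, rt_ms``.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    rt_model = rt_model or RTModel()
    rng = _rng(seed)
    E = bank.n_events
    yes = rng.random((n_participants, E)) < bank.p_yes
    lo, hi = rt_model.mid_band
    mid = (bank.p_yes > lo) & (bank.p_yes < hi)
    rt = (
        rt_model.base_ms
        + rt_model.mid_shift_ms * mid
        + rng.normal(0.0, rt_model.sd_ms, size=(n_participants, E))
    )
    rt = np.maximum(rt, rt_model.floor_ms)
    pid = np.repeat(np.arange(1, n_participants + 1), E)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "event_id": np.tile(bank.event_id, n_participants),
            "response": np.where(yes.ravel(), "yes", "no"),
            "rt_ms": rt.ravel(),
        }
    )


def sample_ground_truth(
    n_nodes: int = 42,
    n_participants: int = 113,
    n_hubs: int = 4,
    hub_nodes=None,
    gain_mean: float = 0.65,
    gain_sd: float = 0.2,
    memory_slope: float = 2.0,
    base_corr: float = 0.2,
    spillover: float = 0.3,
    n_affiliates: int = 0,
    n_factors: int = 6,
    factor_sd: float = 0.15,
    neighbor_corr: float = 0.55,
    neighbor_decay: float = 0.5,
    seed=None,
) -> GroundTruth:
    """Draw a planted-effect configuration.

    The baseline covariance is a unit-diagonal mixture of (a) a weak common
    correlation ``base_corr``, (b) a factor model (loadings N(0, factor_sd)
    on ``n_factors`` latent signals, row norms capped) giving the stable
    edge hierarchy functional connectivity matrices show in practice, and
    (c) distance-decay community structure (``neighbor_corr`` for adjacent
    nodes on a ring, decaying by ``neighbor_decay`` per step) so that every
    node has a few reliably strong partners.  Without (b) and (c),
    density-thresholded graphs degenerate into near-random graphs whose
    closeness values are dominated by fluctuating disconnection, which no
    empirical connectome resembles.  Setting ``n_factors=0`` and
    ``neighbor_corr=0`` recovers the exchangeable compound-symmetric
    baseline.  Per-participant coupling gains are truncated-normal (negative
    draws clipped to zero).
    """
    rng = _rng(seed)
    if hub_nodes is None:
        hub_nodes = rng.choice(n_nodes, size=n_hubs, replace=False)
    hub_nodes = np.sort(np.asarray(hub_nodes, dtype=int))
    gains = np.maximum(rng.normal(gain_mean, gain_sd, size=n_participants), 0.0)
    cov = np.full((n_nodes, n_nodes), float(base_corr))
    if n_factors > 0:
        L = rng.normal(0.0, factor_sd, size=(n_nodes, n_factors))
        norms = np.linalg.norm(L, axis=1)
        cap = np.sqrt(max(0.8 - base_corr, 0.0))
        scale = np.minimum(1.0, cap / np.maximum(norms, 1e-12))
        L = L * scale[:, None]
        cov = cov + L @ L.T
    if neighbor_corr > 0:
        # distance-decay community structure on a ring: every node keeps a
        # few reliably strong partners, as cortical parcellations do
        idx = np.arange(n_nodes)
        ring = np.minimum(np.abs(idx[:, None] - idx[None, :]),
                          n_nodes - np.abs(idx[:, None] - idx[None, :]))
        decay = neighbor_corr * neighbor_decay ** (ring - 1.0)
        decay[ring == 0] = 0.0
        cov = cov + decay
    np.fill_diagonal(cov, 1.0)
    # guarantee a valid correlation matrix: clip negative eigenvalues and
    # renormalize the diagonal
    w, V = np.linalg.eigh(cov)
    if w.min() < 1e-8:
        cov = (V * np.maximum(w, 1e-8)) @ V.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        cov = (cov + cov.T) / 2.0
    # affiliates: mid-connectivity nodes - deep processing recruits regions
    # into coordination with the hub network that are neither its tightest
    # partners already nor the network's most peripheral members
    others = np.setdiff1d(np.arange(n_nodes), hub_nodes)
    strength = np.abs(cov[others] - np.eye(n_nodes)[others]).mean(axis=1)
    order = others[np.argsort(strength)]
    k = min(n_affiliates, len(others))
    start = max((len(others) - k) // 2, 0)
    affiliates = np.sort(order[start:start + k])
    # spread affiliates round-robin over the hubs so every hub recruits an
    # equal share
    aff_hub = np.arange(len(affiliates)) % max(len(hub_nodes), 1)
    return GroundTruth(
        hub_nodes=hub_nodes,
        coupling_gain=gains,
        memory_slope=memory_slope,
        base_covariance=cov,
        spillover=spillover,
        affiliates=affiliates,
        affiliate_hub=aff_hub,
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_memory_outcomes(
    responses: pd.DataFrame,
    effects: MemoryEffects | None = None,
    ground_truth: GroundTruth | None = None,
    seed=None,
) -> pd.DataFrame:
    """Simulate the three-question test phase for every encoded event.

    Full source memory (Q1 "yes", Q2 "yes", Q3 correct) follows a logistic
    model on the event's elaboration level (from pooled responses), the
    participant's congruity level (their own yes/no), and a participant
    ability term ``memory_slope * coupling_gain + noise`` centered on the
    cohort mean.  Items without true source memory can still be recognized
    (Q1 "yes"), can claim action memory (Q2 "yes") and then guess Q3 at
    chance, which is what the corrected source score later compensates for.
    One foil item per encoded event yields false alarms for d'.

    Returns a long table with columns
    ``participant_id, item_id, old, q1, q2, q3``.
    """
    from . import behavior  # deferred: behavior does not import simulate

    effects = effects or MemoryEffects()
    rng = _rng(seed)
    participants = np.sort(responses["participant_id"].unique())
    P = len(participants)
    events = np.sort(responses["event_id"].unique())
    E = len(events)
    if responses.groupby("participant_id")["event_id"].nunique().min() != E:
        raise ValueError("responses must cover every event for every participant")

    elab = behavior.classify_elaboration(behavior.rank_events(responses))
    high_elab = set(elab.loc[elab["level"] == "high", "event_id"])
    z_e = np.array([0.5 if e in high_elab else -0.5 for e in events])

    if ground_truth is not None:
        if len(ground_truth.coupling_gain) != P:
            raise ValueError("ground truth covers a different number of participants")
        gain = ground_truth.coupling_gain
        slope = ground_truth.memory_slope
    else:
        gain = np.zeros(P)
        slope = 0.0
    ability = slope * (gain - gain.mean()) + rng.normal(0, effects.ability_sd, size=P)

    # participant x event matrix of own yes-responses -> congruity code
    wide = responses.pivot(index="participant_id", columns="event_id", values="response")
    wide = wide.reindex(index=participants, columns=events)
    z_c = np.where(wide.to_numpy() == "yes", 0.5, -0.5)

    logit = effects.base_logit + effects.elab_effect * z_e[None, :] + effects.congr_effect * z_c
    logit = logit + ability[:, None]
    source = rng.random((P, E)) < _sigmoid(logit)

    p_rec = _sigmoid(effects.recognition_logit + ability)[:, None]
    rec_only = ~source & (rng.random((P, E)) < p_rec)
    q2_claim = rec_only & (rng.random((P, E)) < effects.q2_rate_nosource)
    guess_correct = rng.random((P, E)) < 0.5

    q1 = np.where(source | rec_only, "yes", "no")
    q2 = np.where(source, "yes", np.where(q2_claim, "yes", np.where(rec_only, "no", "absent")))
    q3 = np.where(
        source,
        "correct",
        np.where(q2_claim & guess_correct, "correct", np.where(q2_claim, "wrong", "absent")),
    )

    old = pd.DataFrame(
        {
            "participant_id": np.repeat(participants, E),
            "item_id": np.tile(events, P),
            "old": True,
            "q1": q1.ravel(),
            "q2": q2.ravel(),
            "q3": q3.ravel(),
        }
    )
    foil_ids = np.arange(events.max() + 1, events.max() + 1 + E)
    fa = rng.random((P, E)) < effects.foil_fa_rate
    new = pd.DataFrame(
        {
            "participant_id": np.repeat(participants, E),
            "item_id": np.tile(foil_ids, P),
            "old": False,
            "q1": np.where(fa.ravel(), "yes", "no"),
            "q2": "absent",
            "q3": "absent",
        }
    )
    return pd.concat([old, new], ignore_index=True)


def _fit_iti_weights(values: np.ndarray, target_mean: float) -> np.ndarray:
    """Geometric weights w_k proportional to r**k matching the target mean."""
    values = np.asarray(values, dtype=float)
    if len(values) == 1:
        if not np.isclose(values[0], target_mean):
            raise ValueError("single ITI value cannot match the requested mean")
        return np.array([1.0])
    lo, hi = values.min(), values.max()
    if not lo < target_mean < hi:
        raise ValueError(
            f"target mean {target_mean} outside the open interval ({lo}, {hi}) "
            "spanned by the ITI support"
        )
    k = np.arange(len(values))

    def mean_at(log_r):
        w = np.exp(k * log_r)
        w /= w.sum()
        return float(w @ values) - target_mean

    log_r = optimize.brentq(mean_at, -40.0, 40.0)
    w = np.exp(k * log_r)
    return w / w.sum()


def generate_design(
    n_events: int = 50,
    tr: float = 2.39,
    iti_spec: ITISpec | None = None,
    seed=None,
    n_volumes: int = 131,
    event_duration: float = 2.0,
    max_attempts: int = 100,
) -> DesignSpec:
    """Draw a jittered event-related design for one run.

    ITIs take 4 discrete values in [1, 7] s with exponentially decaying
    probabilities calibrated so the mean ITI matches ``iti_spec.target_mean``
    (default 2.98 s); events last ``event_duration`` seconds.  Draws are
    rejected (and redrawn, deterministically under the seed) if the events
    would not fit into the run.
    """
    iti_spec = iti_spec or ITISpec()
    values = np.asarray(iti_spec.values, dtype=float)
    weights = _fit_iti_weights(values, iti_spec.target_mean)
    rng = _rng(seed)
    scan_length = n_volumes * tr
    for _ in range(max_attempts):
        itis = rng.choice(values, size=n_events, p=weights)
        onsets = itis[0] + np.concatenate([[0.0], np.cumsum(event_duration + itis[1:])])
        if onsets[-1] + event_duration <= scan_length:
            return DesignSpec(
                tr=tr,
                n_volumes=n_volumes,
                onsets=onsets,
                durations=np.full(n_events, event_duration),
            )
    raise ValueError(
        f"could not place {n_events} events of {event_duration}s in a "
        f"{scan_length:.0f}s run after {max_attempts} attempts"
    )


def draw_itis(n: int, iti_spec: ITISpec | None = None, seed=None) -> np.ndarray:
    """Draw bare ITI values from the calibrated discrete distribution."""
    iti_spec = iti_spec or ITISpec()
    values = np.asarray(iti_spec.values, dtype=float)
    weights = _fit_iti_weights(values, iti_spec.target_mean)
    return _rng(seed).choice(values, size=n, p=weights)


def generate_node_timeseries(
    design: DesignSpec,
    truth: GroundTruth,
    labels,
    noise: NoiseSpec | None = None,
    seed=None,
    participant: int = 0,
    deep_label: str = "high",
    microtime: int = 16,
    hrf_params: HRFParams | None = None,
    participant_id: int | None = None,
    evoked_sd: float = 1.0,
) -> NodeTimeSeries:
    """Forward-simulate BOLD-like node signals for one participant/run.

    Neural activity is multivariate noise with covariance
    ``truth.base_covariance`` on a microtime grid (``tr / microtime``).
    During events labeled ``deep_label`` a shared standard-normal latent
    input, scaled by the participant's coupling gain, is added to the hub
    nodes - the planted condition-dependent coupling.  The neural signals are
    convolved with the canonical HRF, sampled at the TR, and corrupted with
    AR(1) observation noise.
    """
    noise = noise or NoiseSpec()
    labels = np.asarray(labels)
    if len(labels) != design.n_events:
        raise ValueError("labels must cover every event in the design")
    rng = _rng(seed)
    n_nodes = truth.n_nodes
    dt = design.tr / microtime
    n_micro = design.n_volumes * microtime

    try:
        L = np.linalg.cholesky(truth.base_covariance)
    except np.linalg.LinAlgError as err:
        raise ValueError("base_covariance must be positive semi-definite") from err

    # background: stationary multivariate noise with the baseline covariance
    neural = L @ rng.standard_normal((n_nodes, n_micro))

    # evoked responses: every event elicits a per-node amplitude vector with
    # the same baseline covariance, held constant over the event - the
    # trial-by-trial co-activation that task-modulated connectivity actually
    # measures (event-scale content survives the HRF's low-pass and is
    # recoverable by deconvolution, unlike the fast background)
    windows = [
        (int(np.floor(onset / dt)), min(int(np.ceil((onset + dur) / dt)), n_micro))
        for onset, dur in zip(design.onsets, design.durations)
    ]
    amps = L @ rng.standard_normal((n_nodes, design.n_events))
    amps = evoked_sd * amps

    gain = float(truth.coupling_gain[participant])
    deep_mask = labels == deep_label
    if gain > 0 and deep_mask.any() and len(truth.hub_nodes):
        # deep-processing coupling, applied to the evoked amplitudes of deep
        # events only and variance-preserving: each hub's evoked amplitude
        # is pulled toward the network's common evoked signal for that
        # event, so the hub synchronizes with the network at large - the
        # operational meaning of "becoming more central".  Optionally, each
        # affiliate additionally mixes in a copy of its hub's amplitude.
        deep_idx = np.flatnonzero(deep_mask)
        c_hub = min(gain, 0.95)
        if c_hub > 0:
            common = amps[:, deep_idx].mean(axis=0)
            sd = common.std()
            if sd > 0:
                g = common / sd * evoked_sd
                amps[np.ix_(truth.hub_nodes, deep_idx)] = (
                    np.sqrt(1 - c_hub**2) * amps[np.ix_(truth.hub_nodes, deep_idx)]
                    + c_hub * g
                )
        c_aff = min(truth.spillover * gain, 0.95)
        if len(truth.affiliates) and c_aff > 0:
            hub_amp = amps[truth.hub_nodes[truth.affiliate_hub]][:, deep_idx]
            amps[np.ix_(truth.affiliates, deep_idx)] = (
                np.sqrt(1 - c_aff**2) * amps[np.ix_(truth.affiliates, deep_idx)]
                + c_aff * hub_amp
            )
    for e, (i0, i1) in enumerate(windows):
        neural[:, i0:i1] += amps[:, e][:, None]

    hrf = canonical_hrf(dt, hrf_params)
    bold = signal.fftconvolve(neural, hrf[None, :], axes=1)[:, :n_micro]
    bold = bold[:, ::microtime]

    if noise.sigma > 0:
        w = rng.standard_normal((n_nodes, design.n_volumes))
        if noise.ar1_rho:
            w = signal.lfilter([1.0], [1.0, -noise.ar1_rho], w, axis=1)
            w *= np.sqrt(1.0 - noise.ar1_rho**2)
        bold = bold + noise.sigma * w
    elif noise.ar1_rho and noise.sigma == 0:
        warnings.warn("sigma=0: AR(1) parameter has no effect", stacklevel=2)

    return NodeTimeSeries(
        participant_id=participant if participant_id is None else participant_id,
        data=bold,
        tr=design.tr,
    )
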