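"""Synthetic cohorts with planted covariance, effects, and geometry.

Emulates the study design the analysis stages expect: two groups
(drug / placebo, default 20 / 19 subjects) scanned pre and post an
intervention, 240 frames at TR = 1.8 s, 400 parcels spread over six
resting-state networks. Each scan is a zero-mean multivariate normal
draw with a block covariance determined by within-network and
between-network couplings plus any injected group x session effects,
optionally AR(1)-smoothed in time (the same filter on every parcel, so
all planted cross-correlations are preserved exactly).

Coupling convention: ``between_coupling`` values and injected deltas
are the target correlations between NETWORK-MEAN series, not between
individual parcel pairs. Averaging k parcels with within-coupling w
shrinks the mean's variance to v = (1 + (k-1) w) / k, so the generator
places b * sqrt(v_a v_b) in each parcel block to make the network-mean
correlation come out exactly b. This keeps every closed-form truth used
by recovery tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ANALYZED_NETWORKS, FCMatrix, NetworkAtlas, ParcelTimeSeries

#: Parcels per network for the default 400-parcel cortex, proportional to
#: the Schaefer-400/Yeo-7 allocation with the limbic network removed.
_NETWORK_PROPORTIONS = {
    "VIS": 61, "ASM": 77, "DAN": 46, "SAL": 47, "FPN": 52, "DMN": 91,
}

#: The five questionnaires modeled in the brain-behavior analyses.
QUESTIONNAIRES = ("MEQ", "EBI", "NADA-S", "PIS", "TMS")


def default_network_sizes(n_parcels: int) -> dict[str, int]:
    """Largest-remainder allocation of parcels across the six networks."""
    total = sum(_NETWORK_PROPORTIONS.values())
    raw = {k: n_parcels * v / total for k, v in _NETWORK_PROPORTIONS.items()}
    sizes = {k: int(np.floor(x)) for k, x in raw.items()}
    leftovers = sorted(raw, key=lambda k: raw[k] - sizes[k], reverse=True)
    for k in leftovers[: n_parcels - sum(sizes.values())]:
        sizes[k] += 1
    return sizes


@dataclass
class EffectInjection:
    """A planted group x session change in one coupling.

    ``target``: a network pair (tuple) for a between-network change, or a
    single network label for a within-network change. ``delta`` is added
    to the corresponding coupling (network-mean correlation scale for
    pairs, parcel-level within-coupling for single networks) for scans of
    ``group`` in ``session``. ``subject_sd`` > 0 draws each subject's
    delta from N(delta, subject_sd).
    """

    target: tuple[str, str] | str
    group: str
    session: str
    delta: float
    subject_sd: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.target, (tuple, list)):
            self.target = tuple(sorted(self.target))
            if len(self.target) != 2 or self.target[0] == self.target[1]:
                raise ValueError(f"bad pair target: {self.target}")

    def applies(self, group: str, session: str) -> bool:
        return self.group == group and self.session == session


@dataclass
class FDParams:
    """Framewise-displacement trace model: |N(mean, sd)| plus rare spikes."""

    mean: float = 0.15
    sd: float = 0.05
    spike_probability: float = 0.03
    spike_magnitude: float = 0.8


@dataclass
class QuestionnaireModel:
    """Linear-Gaussian link from a subject's planted FC change to a score.

    day-2 score = intercept + slope[group] * planted_delta_z + N(0, noise_sd);
    day-1 (baseline) score = intercept + N(0, noise_sd).
    """

    intercept: float = 50.0
    slope_drug: float = 30.0
    slope_placebo: float = 10.0
    noise_sd: float = 8.0

    def slope(self, group: str) -> float:
        return self.slope_drug if group == "drug" else self.slope_placebo


@dataclass
class SimConfig:
    """All knobs of the cohort generator; defaults mirror the study design."""

    n_per_group: tuple[int, int] = (20, 19)  # (drug, placebo)
    n_parcels: int = 400
    network_sizes: dict[str, int] | None = None
    n_frames: int = 240
    tr_seconds: float = 1.8
    within_coupling: float | dict[str, float] = 0.25
    between_coupling: float | dict[tuple[str, str], float] = 0.05
    effect_map: list[EffectInjection] = field(default_factory=list)
    ar1_coefficient: float = 0.3
    fd_params: FDParams = field(default_factory=FDParams)
    questionnaire_model: dict[str, QuestionnaireModel] | None = None
    n_noise_channels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network_sizes is None:
            self.network_sizes = default_network_sizes(self.n_parcels)
        if set(self.network_sizes) != set(ANALYZED_NETWORKS):
            raise ValueError("network_sizes must cover exactly the six networks")
        if sum(self.network_sizes.values()) != self.n_parcels:
            raise ValueError("network_sizes must sum to n_parcels")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if self.questionnaire_model is None:
            self.questionnaire_model = {q: QuestionnaireModel() for q in QUESTIONNAIRES}

    def within_of(self, network: str) -> float:
        if isinstance(self.within_coupling, dict):
            return float(self.within_coupling.get(network, 0.0))
        return float(self.within_coupling)

    def between_of(self, a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        if isinstance(self.between_coupling, dict):
            norm = {tuple(sorted(k)): v for k, v in self.between_coupling.items()}
            return float(norm.get(key, 0.0))
        return float(self.between_coupling)


@dataclass
class CohortTruth:
    """Everything planted, sufficient to recompute every recovery target."""

    config: SimConfig
    group_of: dict[str, str]
    #: subject -> planted atanh-scale post-minus-pre change of the first
    #: injected network pair for the subject's group (0 without injections)
    subject_delta_z: dict[str, float]
    # (group, session) -> 6x6 network-mean correlation matrix
    pair_correlations: dict[tuple[str, str], np.ndarray]

    def expected_pair_r(self, a: str, b: str, group: str, session: str) -> float:
        """Planted correlation between the two networks' mean series."""
        i, j = ANALYZED_NETWORKS.index(a), ANALYZED_NETWORKS.index(b)
        return float(self.pair_correlations[(group, session)][i, j])

    def expected_pair_z(self, a: str, b: str, group: str, session: str) -> float:
        return float(np.arctanh(self.expected_pair_r(a, b, group, session)))


@dataclass
class CohortDataset:
    """Scans, design metadata, atlas, scores, and the planted truth."""

    scans: dict[tuple[str, str], ParcelTimeSeries]  # (subject, session) ->
    group_of: dict[str, str]
    atlas: NetworkAtlas
    scores: pd.DataFrame  # subject, group, day, questionnaire, value
    truth: CohortTruth

    @property
    def subjects(self) -> list[str]:
        return sorted(self.group_of)

    def scans_of_session(self, session: str) -> dict[str, ParcelTimeSeries]:
        return {s: self.scans[(s, session)] for s in self.subjects}


def _network_correlation_matrix(
    config: SimConfig, group: str, session: str, rng: np.random.Generator | None
) -> tuple[np.ndarray, dict[str, float]]:
    """(6x6 network-mean correlations, per-network within-couplings)."""
    nets = ANALYZED_NETWORKS
    within = {n: config.within_of(n) for n in nets}
    pair_r = np.eye(len(nets))
    for i, a in enumerate(nets):
        for j in range(i + 1, len(nets)):
            pair_r[i, j] = pair_r[j, i] = config.between_of(a, nets[j])
    for inj in config.effect_map:
        if not inj.applies(group, session):
            continue
        delta = inj.delta
        if inj.subject_sd > 0 and rng is not None:
            delta = delta + rng.normal(0.0, inj.subject_sd)
        if isinstance(inj.target, tuple):
            i, j = nets.index(inj.target[0]), nets.index(inj.target[1])
            pair_r[i, j] += delta
            pair_r[j, i] = pair_r[i, j]
        else:
            within[inj.target] += delta
    return pair_r, within


def _build_covariance(
    config: SimConfig, pair_r: np.ndarray, within: dict[str, float]
) -> np.ndarray:
    """Parcel-level block covariance from network-level couplings."""
    nets = ANALYZED_NETWORKS
    sizes = [config.network_sizes[n] for n in nets]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    p = offsets[-1]
    sigma = np.zeros((p, p))
    v = {}
    for n, k in zip(nets, sizes):
        w = within[n]
        if not -1.0 / max(k - 1, 1) < w < 1.0:
            raise ValueError(f"within-coupling {w} for {n} is not feasible for k={k}")
        v[n] = (1.0 + (k - 1) * w) / k
    for i, a in enumerate(nets):
        ka = sizes[i]
        block = np.full((ka, ka), within[a])
        np.fill_diagonal(block, 1.0)
        sigma[offsets[i]:offsets[i + 1], offsets[i]:offsets[i + 1]] = block
        for j in range(i + 1, len(nets)):
            b = nets[j]
            r = pair_r[i, j]
            if not -1.0 < r < 1.0:
                raise ValueError(f"network-mean correlation {r} for {a}-{b} out of (-1,1)")
            val = r * np.sqrt(v[a] * v[b])
            sigma[offsets[i]:offsets[i + 1], offsets[j]:offsets[j + 1]] = val
            sigma[offsets[j]:offsets[j + 1], offsets[i]:offsets[i + 1]] = val
    return sigma


def _cholesky_or_raise(sigma: np.ndarray, context: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"implied parcel covariance is not positive definite for {context}; "
            "reduce the offending injection deltas or couplings"
        ) from None


def _checked_cholesky(
    config: SimConfig, pair_r: np.ndarray, within: dict[str, float], context: str
) -> np.ndarray:
    """Build + factor the covariance, attaching design-cell context to
    any infeasibility (out-of-range coupling or non-PD matrix)."""
    try:
        sigma = _build_covariance(config, pair_r, within)
    except ValueError as exc:
        raise ValueError(f"{exc} ({context})") from None
    return _cholesky_or_raise(sigma, context)


def _ar1_smooth(e: np.ndarray, phi: float) -> np.ndarray:
    """x_0 = e_0 (stationary start); x_t = phi x_{t-1} + sqrt(1-phi^2) e_t."""
    if phi == 0.0:
        return e
    from scipy.signal import lfilter

    scaled = np.sqrt(1.0 - phi**2) * e
    scaled[0] = e[0]  # stationary initial condition
    return lfilter([1.0], [1.0, -phi], scaled, axis=0)


def _make_atlas(config: SimConfig) -> tuple[NetworkAtlas, list[str]]:
    parcel_ids, mapping = [], {}
    idx = 1
    for net in ANALYZED_NETWORKS:
        for _ in range(config.network_sizes[net]):
            pid = f"P{idx:04d}"
            parcel_ids.append(pid)
            mapping[pid] = net
            idx += 1
    return NetworkAtlas(mapping=mapping), parcel_ids


def simulate_scan(
    config: SimConfig,
    cholesky: np.ndarray,
    parcel_ids: list[str],
    rng: np.random.Generator,
) -> ParcelTimeSeries:
    """One scan: MVN draw, AR(1) smoothing, FD trace, motion, noise channels."""
    t, p = config.n_frames, config.n_parcels
    e = rng.standard_normal((t, p)) @ cholesky.T
    data = _ar1_smooth(e, config.ar1_coefficient)

    fdp = config.fd_params
    fd = np.abs(rng.normal(fdp.mean, fdp.sd, t))
    spikes = rng.random(t) < fdp.spike_probability
    fd[spikes] += fdp.spike_magnitude

    motion = np.cumsum(rng.normal(0.0, 0.02, (t, 6)), axis=0)
    shared = rng.standard_normal((t, 1))
    noise = 0.6 * shared + 0.8 * rng.standard_normal((t, config.n_noise_channels))

    return ParcelTimeSeries(
        data=data,
        tr_seconds=config.tr_seconds,
        parcel_ids=parcel_ids,
        motion=motion,
        fd=fd,
        noise_signals=noise,
    )


def simulate_cohort(config: SimConfig) -> CohortDataset:
    """Generate a full two-group, two-session cohort from one seed.

    Identical config and seed yield a bit-identical dataset. Raises if
    any implied covariance (any group x session cell, any subject) is
    not positive definite, naming the injections in play.
    """
    rng = np.random.default_rng(config.seed)
    atlas, parcel_ids = _make_atlas(config)

    # validate all four design cells up front with the mean deltas
    for group in ("drug", "placebo"):
        for session in ("pre", "post"):
            pair_r, within = _network_correlation_matrix(config, group, session, None)
            inj_names = [
                f"{i.target}:{i.group}:{i.session}"
                for i in config.effect_map
                if i.applies(group, session)
            ]
            ctx = f"cell ({group}, {session})" + (
                f" with injections {inj_names}" if inj_names else ""
            )
            _checked_cholesky(config, pair_r, within, ctx)

    subjects: list[tuple[str, str]] = []
    for g, n in zip(("drug", "placebo"), config.n_per_group):
        subjects += [(f"{g}{i + 1:02d}", g) for i in range(n)]
    group_of = dict(subjects)

    scans: dict[tuple[str, str], ParcelTimeSeries] = {}
    subject_deltas: dict[tuple[str, int], dict[str, float]] = {}
    pair_corrs: dict[tuple[str, str], np.ndarray] = {}
    for group in ("drug", "placebo"):
        for session in ("pre", "post"):
            pair_r, _ = _network_correlation_matrix(config, group, session, None)
            pair_corrs[(group, session)] = pair_r

    has_subject_sd = any(i.subject_sd > 0 for i in config.effect_map)
    chol_cache: dict[tuple[str, str], np.ndarray] = {}
    subject_delta_z: dict[str, float] = {}
    for subject, group in subjects:
        for session in ("pre", "post"):
            key = (group, session)
            if has_subject_sd:
                pair_r, within = _network_correlation_matrix(
                    config, group, session, rng
                )
                chol = _checked_cholesky(
                    config, pair_r, within, f"subject {subject} {session}"
                )
            else:
                if key not in chol_cache:
                    pair_r, within = _network_correlation_matrix(
                        config, group, session, None
                    )
                    chol_cache[key] = _checked_cholesky(
                        config, pair_r, within, f"cell {key}"
                    )
                chol = chol_cache[key]
                pair_r = pair_corrs[key]
            scans[(subject, session)] = simulate_scan(config, chol, parcel_ids, rng)
            if session == "post":
                subject_delta_z[subject] = _first_injection_delta_z(
                    config, pair_r, pair_corrs[(group, "pre")], group
                )

    scores = _simulate_scores(config, group_of, subject_delta_z, rng)
    truth = CohortTruth(
        config=config,
        group_of=group_of,
        subject_delta_z=subject_delta_z,
        pair_correlations=pair_corrs,
    )
    return CohortDataset(
        scans=scans, group_of=group_of, atlas=atlas, scores=scores, truth=truth
    )


def _first_injection_delta_z(
    config: SimConfig,
    pair_r_post: np.ndarray,
    pair_r_pre: np.ndarray,
    group: str,
) -> float:
    """atanh-scale post-minus-pre change of the first injected pair.

    This is the planted FC change the questionnaire model links to; 0
    when the cohort carries no pair injection for the subject's group.
    """
    for inj in config.effect_map:
        if isinstance(inj.target, tuple) and inj.group == group:
            i = ANALYZED_NETWORKS.index(inj.target[0])
            j = ANALYZED_NETWORKS.index(inj.target[1])
            return float(np.arctanh(pair_r_post[i, j]) - np.arctanh(pair_r_pre[i, j]))
    return 0.0


def _simulate_scores(
    config: SimConfig,
    group_of: dict[str, str],
    subject_delta_z: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for subject in sorted(group_of):
        group = group_of[subject]
        for quest, model in config.questionnaire_model.items():
            base = model.intercept + rng.normal(0.0, model.noise_sd)
            day2 = (
                model.intercept
                + model.slope(group) * subject_delta_z.get(subject, 0.0)
                + rng.normal(0.0, model.noise_sd)
            )
            rows.append((subject, group, 1, quest, base))
            rows.append((subject, group, 2, quest, day2))
    return pd.DataFrame(
        rows, columns=["subject", "group", "day", "questionnaire", "value"]
    )


def simulate_gradient_connectome(
    n_parcels: int,
    geometry: str = "line",
    decay: float = 5.0,
    seed: int = 0,
    within: float = 0.6,
    between: float = 0.05,
    noise_sd: float = 0.01,
) -> tuple[FCMatrix, np.ndarray]:
    """Connectome with a known low-dimensional organization.

    ``line``: connectivity decays exponentially with distance along a
    planted 1-D coordinate (r_ij = exp(-decay |s_i - s_j|)); returns the
    coordinate. ``two_block``: strong within-block (``within``), weak
    between-block (``between``) correlation, plus a small set of hub
    parcels per block — a few percent of parcels with elevated coupling
    to their whole block, two of which also couple moderately to the
    opposite block. Hubs concentrate each row's strongest edges on a
    shared support, and the bridge hubs keep the thresholded graph
    connected, mirroring how hub regions tie real connectomes together;
    without them, row-sparsified block matrices fall apart into
    disconnected components. Returns 0/1 block labels.
    Small symmetric Gaussian noise (sd ``noise_sd``) breaks exact
    degeneracies; a fixed seed gives an identical matrix.
    """
    if n_parcels < 10:
        raise ValueError("need at least 10 parcels")
    rng = np.random.default_rng(seed)
    if geometry == "line":
        if decay <= 0:
            raise ValueError("decay must be positive")
        s = np.linspace(0.0, 1.0, n_parcels)
        r = np.exp(-decay * np.abs(s[:, None] - s[None, :]))
        planted = s
    elif geometry == "two_block":
        labels = np.zeros(n_parcels, dtype=int)
        labels[n_parcels // 2 :] = 1
        same = labels[:, None] == labels[None, :]
        r = np.where(same, within, between).astype(float)
        block_a = np.flatnonzero(labels == 0)
        block_b = np.flatnonzero(labels == 1)
        n_hub = max(3, round(0.06 * n_parcels))
        n_bridge = max(2, n_hub // 3)
        for block in (block_a, block_b):
            hubs = block[:n_hub]
            for h in hubs:
                r[h, block] = within + 0.15
                r[block, h] = within + 0.15
            r[np.ix_(hubs, hubs)] = within + 0.30
        for block, other in ((block_a, block_b), (block_b, block_a)):
            for h in block[:n_bridge]:
                r[h, other] = np.maximum(r[h, other], within + 0.05)
                r[other, h] = r[h, other]
        planted = labels
    else:
        raise ValueError(f"unknown geometry: {geometry!r}")
    noise = rng.normal(0.0, noise_sd, (n_parcels, n_parcels))
    r = r + (noise + noise.T) / 2.0
    np.fill_diagonal(r, 1.0)
    cap = 1.0 - 1e-5
    z = np.arctanh(np.clip(r, -cap, cap))
    np.fill_diagonal(z, 0.0)
    parcel_ids = [f"P{i + 1:04d}" for i in range(n_parcels)]
    fc = FCMatrix(values=(z + z.T) / 2.0, parcel_ids=parcel_ids)
    return fc, planted
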