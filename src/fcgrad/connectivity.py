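"""Functional-connectivity metrics on denoised parcel time series.

All correlations are Pearson r over retained (unscrubbed) frames,
capped at |r| <= 1 - cap_epsilon and Fisher z-transformed (atanh).
Metrics: the full parcel x parcel matrix, per-network seed maps,
within-network FC, the 6 x 6 between-network matrix, and per-parcel
global FC (row mean excluding the diagonal).
"""

from __future__ import annotations

import numpy as np

from .types import ANALYZED_NETWORKS, FCMatrix, NetworkAtlas, ParcelTimeSeries, SeedMap

CAP_EPSILON = 1e-5
MIN_FRAMES = 10


def fisher_z(r: np.ndarray | float, cap_epsilon: float = CAP_EPSILON) -> np.ndarray:
    """atanh with the |r| cap applied; returns capped count via .n_capped on arrays."""
    r = np.asarray(r, dtype=float)
    cap = 1.0 - cap_epsilon
    return np.arctanh(np.clip(r, -cap, cap))


def _retained_checked(ts: ParcelTimeSeries) -> np.ndarray:
    x = ts.retained()
    if x.shape[0] < MIN_FRAMES:
        raise ValueError(
            f"only {x.shape[0]} retained frames; need at least {MIN_FRAMES}"
        )
    constant = np.ptp(x, axis=0) == 0  # exact, unlike std of a constant
    if np.any(constant):
        bad = [ts.parcel_ids[i] for i in np.flatnonzero(constant)]
        raise ValueError(f"constant parcel time series: {bad}")
    return x


def fc_matrix(ts: ParcelTimeSeries, cap_epsilon: float = CAP_EPSILON) -> FCMatrix:
    """Fisher-z Pearson correlation between all parcel pairs."""
    x = _retained_checked(ts)
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    cap = 1.0 - cap_epsilon
    off = ~np.eye(len(r), dtype=bool)
    n_capped = int(np.count_nonzero(np.abs(r[off]) > cap)) // 2
    z = np.arctanh(np.clip(r, -cap, cap))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(
        values=z,
        parcel_ids=list(ts.parcel_ids),
        cap_epsilon=cap_epsilon,
        diagonal_excluded=True,
        n_capped=n_capped,
    )


def network_mean_series(
    ts: ParcelTimeSeries, atlas: NetworkAtlas, network: str
) -> np.ndarray:
    """Unweighted mean of the network's parcel series over retained frames."""
    idx = atlas.indices_of(network, ts.parcel_ids)
    if len(idx) == 0:
        raise ValueError(f"network {network} has no parcels in this scan")
    return ts.retained()[:, idx].mean(axis=1)


def network_seed_map(
    ts: ParcelTimeSeries,
    atlas: NetworkAtlas,
    network: str,
    cap_epsilon: float = CAP_EPSILON,
) -> SeedMap:
    """Fisher-z correlation of every parcel with one network's mean series."""
    x = _retained_checked(ts)
    seed = network_mean_series(ts, atlas, network)
    seed_c = seed - seed.mean()
    xc = x - x.mean(axis=0)
    denom = np.sqrt((seed_c**2).sum()) * np.sqrt((xc**2).sum(axis=0))
    r = (xc.T @ seed_c) / denom
    return SeedMap(
        network_label=network,
        values=fisher_z(r, cap_epsilon),
        parcel_ids=list(ts.parcel_ids),
    )


def within_network_fc(seed_map: SeedMap, atlas: NetworkAtlas) -> float:
    """Mean seed-map value over the seed network's own parcels.

    Own-network parcels are included, mirroring masking a network FC
    map with the network's own mask.
    """
    idx = atlas.indices_of(seed_map.network_label, seed_map.parcel_ids)
    return float(np.mean(seed_map.values[idx]))


def between_network_fc(
    ts: ParcelTimeSeries, atlas: NetworkAtlas, cap_epsilon: float = CAP_EPSILON
) -> np.ndarray:
    """6 x 6 Fisher-z matrix of correlations between network-mean series.

    Rows/columns follow :data:`~fcgrad.types.ANALYZED_NETWORKS` order;
    the diagonal (a network with itself) is set to 0 and excluded from
    analysis.
    """
    _retained_checked(ts)
    means = np.column_stack(
        [network_mean_series(ts, atlas, net) for net in ANALYZED_NETWORKS]
    )
    r = np.corrcoef(means, rowvar=False)
    r = (r + r.T) / 2.0
    z = fisher_z(r, cap_epsilon)
    np.fill_diagonal(z, 0.0)
    return z


def global_fc(fc: FCMatrix) -> np.ndarray:
    """Per-parcel mean Fisher-z connectivity with all other parcels."""
    v = fc.values.copy()
    np.fill_diagonal(v, 0.0)
    p = fc.n_parcels
    return v.sum(axis=1) / (p - 1)
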