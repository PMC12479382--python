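"""Plain-text I/O: TSV tables for every artifact, YAML/JSON config.

Everything starts at parcel resolution, so no imaging containers are
needed; users who parcellate their own imaging data upstream can write
the frames x parcels TSV defined here and enter the pipeline at the
denoising stage. All writers emit tab-separated text with fixed
decimal formatting (%.10g) so identical runs produce identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ANALYZED_NETWORKS, FCMatrix, GradientSet, NetworkAtlas, ParcelTimeSeries

FLOAT_FMT = "%.10g"

MOTION_COLUMNS = ["motion_tx", "motion_ty", "motion_tz",
                  "motion_rx", "motion_ry", "motion_rz"]
FD_COLUMN = "framewise_displacement"


def write_timeseries(ts: ParcelTimeSeries, path: str | Path) -> None:
    """Frames x parcels TSV; header row carries the parcel IDs."""
    df = pd.DataFrame(ts.data, columns=list(ts.parcel_ids))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_confounds(ts: ParcelTimeSeries, path: str | Path) -> None:
    """Motion (6 columns), FD, and noise channels as one TSV."""
    cols: dict[str, np.ndarray] = {}
    if ts.motion is not None:
        for i, name in enumerate(MOTION_COLUMNS):
            cols[name] = ts.motion[:, i]
    if ts.fd is not None:
        cols[FD_COLUMN] = ts.fd
    if ts.noise_signals is not None:
        for i in range(ts.noise_signals.shape[1]):
            cols[f"noise_{i + 1:02d}"] = ts.noise_signals[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_timeseries(
    path: str | Path,
    tr_seconds: float,
    confounds_path: str | Path | None = None,
) -> ParcelTimeSeries:
    """Read a frames x parcels TSV (plus optional confound TSV).

    Raises with the offending identifier or line for duplicate parcel
    IDs, non-numeric cells, or ragged rows.
    """
    path = Path(path)
    seen, raw_dupes = set(), []
    with open(path) as fh:
        raw_ids = fh.readline().rstrip("\n").split("\t")
    for c in raw_ids:
        if c in seen:
            raw_dupes.append(c)
        seen.add(c)
    if raw_dupes:
        raise ValueError(f"duplicate parcel IDs in {path.name}: {sorted(set(raw_dupes))}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    if df.isna().any().any():
        rows = (df.isna().any(axis=1)).to_numpy().nonzero()[0] + 2  # header = line 1
        raise ValueError(f"ragged or missing values in {path.name} at lines {rows.tolist()}")

    motion = fd = noise = None
    if confounds_path is not None:
        cdf = pd.read_csv(confounds_path, sep="\t", dtype=float)
        if all(c in cdf for c in MOTION_COLUMNS):
            motion = cdf[MOTION_COLUMNS].to_numpy()
        if FD_COLUMN in cdf:
            fd = cdf[FD_COLUMN].to_numpy()
        noise_cols = [c for c in cdf.columns if c.startswith("noise_")]
        if noise_cols:
            noise = cdf[noise_cols].to_numpy()
    return ParcelTimeSeries(
        data=df.to_numpy(),
        tr_seconds=tr_seconds,
        parcel_ids=raw_ids,
        motion=motion,
        fd=fd,
        noise_signals=noise,
    )


def write_atlas(atlas: NetworkAtlas, path: str | Path) -> None:
    rows = [(p, l) for p, l in atlas.mapping.items()]
    rows += [(p, l) for p, l in atlas.excluded.items()]
    pd.DataFrame(rows, columns=["parcel_id", "network_label"]).to_csv(
        path, sep="\t", index=False
    )


def read_atlas(path: str | Path) -> NetworkAtlas:
    """Parcel -> network TSV; labels outside the six analyzed networks
    (e.g. LIM) are routed to the excluded list with a warning."""
    import warnings

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"parcel_id", "network_label"} <= set(df.columns):
        raise ValueError("atlas TSV needs parcel_id and network_label columns")
    if df["network_label"].isna().any() or df["parcel_id"].isna().any():
        bad = df.loc[df.isna().any(axis=1), "parcel_id"].tolist()
        raise ValueError(f"parcels missing a label: {bad}")
    mapping, excluded = {}, {}
    for pid, label in zip(df["parcel_id"], df["network_label"]):
        if label in ANALYZED_NETWORKS:
            mapping[pid] = label
        else:
            excluded[pid] = label
    if excluded:
        labels = sorted(set(excluded.values()))
        warnings.warn(
            f"excluding {len(excluded)} parcels with non-analyzed labels {labels}",
            stacklevel=2,
        )
    return NetworkAtlas(mapping=mapping, excluded=excluded)


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fc.values, index=list(fc.parcel_ids), columns=list(fc.parcel_ids))
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="parcel_id")


def read_fc_matrix(path: str | Path) -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    v = df.to_numpy(dtype=float)
    return FCMatrix(values=(v + v.T) / 2.0, parcel_ids=list(df.columns))


def write_gradients(g: GradientSet, path: str | Path) -> None:
    cols = {f"g{i + 1}": g.scores[:, i] for i in range(g.n_components)}
    df = pd.DataFrame({"parcel_id": list(g.parcel_ids), **cols})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_cohort(dataset, out_dir: str | Path) -> None:
    """Write a simulated cohort as the documented TSV bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(dataset.atlas, out / "atlas.tsv")
    write_scores(dataset.scores, out / "scores.tsv")
    for (subject, session), ts in dataset.scans.items():
        write_timeseries(ts, out / f"{subject}_{session}_bold.tsv")
        write_confounds(ts, out / f"{subject}_{session}_confounds.tsv")
    groups = pd.DataFrame(
        sorted(dataset.group_of.items()), columns=["subject", "group"]
    )
    groups.to_csv(out / "groups.tsv", sep="\t", index=False)
    truth = {
        "seed": dataset.truth.config.seed,
        "n_per_group": list(dataset.truth.config.n_per_group),
        "subject_delta_z": dataset.truth.subject_delta_z,
        "pair_correlations": {
            f"{g}_{s}": m.tolist()
            for (g, s), m in dataset.truth.pair_correlations.items()
        },
        "networks": list(ANALYZED_NETWORKS),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


@dataclass
class RunConfig:
    """Resolved parameters of an end-to-end run; defaults are the study's."""

    density: float = 0.10
    alpha: float = 0.5
    n_components: int = 10
    k_analyzed: int = 3
    fd_threshold_mm: float = 0.5
    low_hz: float = 0.008
    high_hz: float = 0.09
    q_level: float = 0.05
    cap_epsilon: float = 1e-5
    procrustes_iterations: int = 10
    gsr: bool = False
    seed: int = 0
    out_dir: str = "fcgrad_run"
    simulate: dict = field(default_factory=dict)

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**data)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
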