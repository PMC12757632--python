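"""Functional connectomes and parcellated time series: construction, validation, I/O.

A region time series is a T x m matrix of frames by regions (parcellated,
minimally preprocessed fMRI).  Its functional connectome (FC) is the m x m
Pearson correlation matrix between region signals: symmetric, unit diagonal,
entries in [-1, 1], positive semidefinite, and of rank at most min(m, T-1)
because correlation centers each column.

File layout (all plain comma-delimited text):

* time series: ``<cohort>/<subject_id>/<session_id>.csv``, rows = frames,
  columns = regions, optional single header row of region ids; sessions are
  named ``ses-1`` and ``ses-2``;
* connectomes: the same convention with square matrices, conventionally
  under an ``fc/`` root;
* atlas: two columns ``region_index,network_name`` with 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .linalg import PSD_TOL, ensure_symmetric, sym_eig

__all__ = [
    "SESSION_IDS",
    "CANONICAL_NETWORKS",
    "RegionTimeSeries",
    "Connectome",
    "NetworkAtlas",
    "Cohort",
    "CensoringReport",
    "clean_timeseries",
    "correlation_fc",
    "truncate_scan",
    "network_submatrix",
    "read_matrix",
    "write_matrix",
    "read_atlas",
    "write_atlas",
    "read_cohort",
    "write_cohort",
    "write_connectome",
]

SESSION_IDS = ("ses-1", "ses-2")

#: the seven canonical resting-state networks (Yeo parcellation order)
CANONICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "control",
    "default_mode",
)


@dataclass
class RegionTimeSeries:
    """Parcellated signal: ``values[t, r]`` is region r at frame t."""

    values: np.ndarray
    subject_id: str = ""
    session_id: str = ""
    region_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D frames x regions array")
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {self.n_frames}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class Connectome:
    """An m x m correlation FC with unit diagonal, validated on construction."""

    values: np.ndarray
    subject_id: str = ""
    session_id: str = ""
    region_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        V = ensure_symmetric(self.values)
        if np.abs(np.diag(V) - 1.0).max(initial=0.0) > 1e-8:
            raise ValueError("connectome diagonal must be 1 (correlation matrix)")
        np.fill_diagonal(V, 1.0)
        if V.min() < -1.0 - 1e-8 or V.max() > 1.0 + 1e-8:
            raise ValueError("connectome entries must lie in [-1, 1]")
        V = np.clip(V, -1.0, 1.0)
        np.fill_diagonal(V, 1.0)
        sym_eig(V, psd_tol=PSD_TOL)  # reject non-PSD input
        self.values = V

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass
class NetworkAtlas:
    """Region -> network labeling; ``labels[r]`` names region r's network."""

    labels: Sequence[str]
    networks: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if not self.labels:
            raise ValueError("atlas must label at least one region")
        if not self.networks:
            seen: dict[str, None] = {}
            for name in self.labels:
                seen.setdefault(name, None)
            self.networks = tuple(seen)
        else:
            self.networks = tuple(self.networks)
            missing = set(self.labels) - set(self.networks)
            if missing:
                raise ValueError(f"labels use unlisted networks: {sorted(missing)}")
        for name in self.networks:
            if name not in self.labels:
                raise ValueError(f"network {name!r} has no regions")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def regions_of(self, network: str) -> np.ndarray:
        """Indices of the network's regions, in original region order."""
        if network not in self.networks:
            raise KeyError(
                f"unknown network {network!r}; available: {', '.join(self.networks)}"
            )
        return np.array([r for r, n in enumerate(self.labels) if n == network])


@dataclass
class Cohort:
    """N subjects, each with exactly two sessions (time series or connectomes)."""

    subjects: Mapping[str, tuple]

    def __post_init__(self) -> None:
        self.subjects = dict(self.subjects)
        if len(self.subjects) < 1:
            raise ValueError("cohort is empty")
        dims = set()
        for sid, sessions in self.subjects.items():
            if len(sessions) != 2:
                raise ValueError(
                    f"subject {sid!r} has {len(sessions)} session(s); exactly 2 required"
                )
            for s in sessions:
                if isinstance(s, RegionTimeSeries):
                    dims.add(s.n_regions)
                elif isinstance(s, Connectome):
                    dims.add(s.dim)
                else:
                    raise TypeError(f"unsupported session payload {type(s).__name__}")
        if len(dims) != 1:
            raise ValueError(f"mixed region dimensions across cohort: {sorted(dims)}")
        self._dim = dims.pop()

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return self._dim

    @property
    def kind(self) -> str:
        first = next(iter(self.subjects.values()))[0]
        return "timeseries" if isinstance(first, RegionTimeSeries) else "fc"

    def sessions(self, index: int) -> Iterator:
        """Yield session ``index`` (0 or 1) for every subject, in id order."""
        for sid in self.subjects:
            yield self.subjects[sid][index]

    def to_connectomes(self) -> "Cohort":
        """Build FCs from time series (identity if already connectomes)."""
        if self.kind == "fc":
            return self
        return Cohort(
            {
                sid: tuple(correlation_fc(ts) for ts in sessions)
                for sid, sessions in self.subjects.items()
            }
        )

    def map_sessions(self, fn) -> "Cohort":
        """Apply ``fn`` to every session payload, keeping the pairing."""
        return Cohort(
            {sid: tuple(fn(s) for s in sessions) for sid, sessions in self.subjects.items()}
        )


@dataclass
class CensoringReport:
    """Which frames list-wise censoring removed, and why it is list-wise."""

    censored_frames: list[int] = field(default_factory=list)
    n_frames_in: int = 0
    n_frames_out: int = 0
    z_thresh: float = 3.0


def clean_timeseries(
    ts: RegionTimeSeries, z_thresh: float = 3.0
) -> tuple[RegionTimeSeries, CensoringReport]:
    """Z-score each region and censor outlier frames list-wise.

    Every region is standardized to mean 0 / sd 1; any frame where some
    region exceeds ``z_thresh`` standard deviations is dropped for all
    regions (one shared temporal mask).  List-wise censoring — rather than
    pairwise-complete correlation — keeps the downstream correlation matrix
    positive semidefinite.
    """
    X = ts.values
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant region signal in region(s) {bad.tolist()}: cannot z-score"
        )
    Z = (X - X.mean(axis=0)) / sd
    mask = np.abs(Z).max(axis=1) <= z_thresh
    censored = np.flatnonzero(~mask).tolist()
    if int(mask.sum()) < 3:
        raise ValueError(
            f"censoring at |z| > {z_thresh} leaves {int(mask.sum())} frames (< 3)"
        )
    report = CensoringReport(
        censored_frames=censored,
        n_frames_in=ts.n_frames,
        n_frames_out=int(mask.sum()),
        z_thresh=z_thresh,
    )
    cleaned = replace(ts, values=Z[mask])
    return cleaned, report


def correlation_fc(ts: RegionTimeSeries) -> Connectome:
    """Pearson-correlation connectome of a region time series.

    Rank is at most min(m, T-1): correlation mean-centers each region, so a
    scan shorter than the parcellation (T <= m) always yields a
    rank-deficient FC.
    """
    if ts.n_frames < 3:
        raise ValueError(f"need at least 3 frames for a correlation FC, got {ts.n_frames}")
    sd = ts.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant region signal in region(s) {bad.tolist()}")
    C = np.corrcoef(ts.values, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return Connectome(
        C,
        subject_id=ts.subject_id,
        session_id=ts.session_id,
        region_ids=ts.region_ids,
    )


def truncate_scan(ts: RegionTimeSeries, k: int) -> RegionTimeSeries:
    """Keep the first ``k`` frames (scan-length / volume-count manipulation)."""
    if not 3 <= k <= ts.n_frames:
        raise ValueError(
            f"k must be in [3, {ts.n_frames}] (frames available), got {k}"
        )
    return replace(ts, values=ts.values[:k].copy())


def network_submatrix(fc: Connectome, atlas: NetworkAtlas, network: str) -> Connectome:
    """Principal submatrix of the FC over one network's regions.

    A principal submatrix of a PSD matrix is PSD, so the result is a valid
    (smaller) connectome; region order is preserved.
    """
    if atlas.n_regions != fc.dim:
        raise ValueError(
            f"atlas labels {atlas.n_regions} regions but FC has {fc.dim}"
        )
    idx = atlas.regions_of(network)
    sub = fc.values[np.ix_(idx, idx)]
    region_ids = (
        [fc.region_ids[i] for i in idx] if fc.region_ids is not None else None
    )
    return Connectome(
        sub,
        subject_id=fc.subject_id,
        session_id=fc.session_id,
        region_ids=region_ids,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O


def _parse_rows(path: Path) -> tuple[np.ndarray, list[str] | None]:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header: list[str] | None = None
    first = [c.strip() for c in lines[0].split(",")]
    try:
        [float(c) for c in first]
    except ValueError:
        header = first
        lines = lines[1:]
    rows: list[list[float]] = []
    width: int | None = None
    for offset, ln in enumerate(lines, start=2 if header else 1):
        cells = [c.strip() for c in ln.split(",")]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}, line {offset}: ragged row ({len(cells)} cells, expected {width})"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}, line {offset}: non-numeric cell ({exc})") from None
    return np.array(rows), header


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric matrix with an optional single header row."""
    return _parse_rows(Path(path))


def write_matrix(
    values: np.ndarray, path: str | Path, header: Sequence[str] | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        if header is not None:
            fh.write(",".join(header) + "\n")
        for row in np.atleast_2d(np.asarray(values, dtype=float)):
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")


def write_connectome(fc: Connectome, path: str | Path) -> None:
    """Serialize an FC; read(write(fc)) round-trips to 1e-12."""
    header = list(fc.region_ids) if fc.region_ids is not None else None
    write_matrix(fc.values, path, header=header)


def read_connectome(path: str | Path, subject_id: str = "", session_id: str = "") -> Connectome:
    values, header = read_matrix(path)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: connectome must be square, got {values.shape}")
    try:
        return Connectome(values, subject_id, session_id, region_ids=header)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_timeseries(
    path: str | Path, subject_id: str = "", session_id: str = ""
) -> RegionTimeSeries:
    values, header = read_matrix(path)
    return RegionTimeSeries(values, subject_id, session_id, region_ids=header)


def read_atlas(path: str | Path) -> NetworkAtlas:
    """Read a two-column ``region_index,network_name`` table (0-based indices)."""
    path = Path(path)
    entries: dict[int, str] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    start = 0
    if lines and lines[0].split(",")[0].strip().lower() in ("region_index", "region"):
        start = 1
    for offset, ln in enumerate(lines[start:], start=start + 1):
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) != 2:
            raise ValueError(f"{path}, line {offset}: expected 2 columns, got {len(cells)}")
        try:
            idx = int(cells[0])
        except ValueError:
            raise ValueError(f"{path}, line {offset}: non-integer region index") from None
        if idx in entries:
            raise ValueError(f"{path}, line {offset}: duplicate region index {idx}")
        entries[idx] = cells[1]
    m = len(entries)
    if sorted(entries) != list(range(m)):
        raise ValueError(f"{path}: region indices must cover 0..{m - 1} exactly once")
    return NetworkAtlas([entries[r] for r in range(m)])


def write_atlas(atlas: NetworkAtlas, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("region_index,network_name\n")
        for r, name in enumerate(atlas.labels):
            fh.write(f"{r},{name}\n")


def read_cohort(path: str | Path, kind: str = "auto") -> Cohort:
    """Read a cohort directory: one subdirectory per subject, two session files.

    ``kind`` is "timeseries", "fc", or "auto" (square matrices with a unit
    diagonal are taken as connectomes).
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"cohort directory not found: {root}")
    subjects: dict[str, tuple] = {}
    for subdir in sorted(p for p in root.iterdir() if p.is_dir()):
        sessions = []
        for ses in SESSION_IDS:
            f = subdir / f"{ses}.csv"
            if not f.exists():
                raise FileNotFoundError(
                    f"subject {subdir.name!r} is missing session file {f.name}"
                )
            values, header = read_matrix(f)
            file_kind = kind
            if file_kind == "auto":
                square = values.shape[0] == values.shape[1]
                unit_diag = square and np.abs(np.diag(values) - 1.0).max() <= 1e-8
                file_kind = "fc" if (square and unit_diag) else "timeseries"
            if file_kind == "fc":
                sessions.append(read_connectome(f, subdir.name, ses))
            else:
                sessions.append(
                    RegionTimeSeries(values, subdir.name, ses, region_ids=header)
                )
        subjects[subdir.name] = tuple(sessions)
    if not subjects:
        raise ValueError(f"no subject directories under {root}")
    return Cohort(subjects)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the directory layout :func:`read_cohort` expects."""
    root = Path(path)
    for sid, sessions in cohort.subjects.items():
        for ses_id, payload in zip(SESSION_IDS, sessions):
            f = root / sid / f"{ses_id}.csv"
            if isinstance(payload, Connectome):
                write_connectome(payload, f)
            else:
                header = (
                    list(payload.region_ids) if payload.region_ids is not None else None
                )
                write_matrix(payload.values, f, header=header)
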