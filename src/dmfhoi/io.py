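"""Domain containers and delimited-text I/O.

Connectomes, region time series, cohorts and run configuration are plain
dataclasses wrapping numpy arrays; everything on disk is delimited text
(CSV/TSV) or JSON so runs are diff-able and portable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "RegionTimeSeries",
    "Cohort",
    "RunConfig",
    "ConnectomeValidationError",
    "NonSquareMatrixError",
    "NonFiniteWeightError",
    "NegativeWeightError",
    "NonzeroDiagonalError",
    "AsymmetricMatrixError",
    "read_connectome",
    "write_connectome",
    "normalize_sc",
    "read_cohort",
    "write_cohort",
    "group_average_connectome",
    "write_results_table",
    "read_results_table",
    "write_run_manifest",
]

#: Largest asymmetry |W - W.T| that is silently symmetrized by averaging.
SYMMETRY_TOL = 1e-9

#: Age bands (years) of the four cohort groups, inclusive lower edge.
GROUP_BANDS = {"I1": (10.0, 20.0), "I2": (20.0, 40.0), "I3": (40.0, 60.0), "I4": (60.0, 80.0)}


class ConnectomeValidationError(ValueError):
    """Base class for structural-connectome validation failures."""


class NonSquareMatrixError(ConnectomeValidationError):
    pass


class NonFiniteWeightError(ConnectomeValidationError):
    pass


class NegativeWeightError(ConnectomeValidationError):
    pass


class NonzeroDiagonalError(ConnectomeValidationError):
    pass


class AsymmetricMatrixError(ConnectomeValidationError):
    pass


@dataclass
class Connectome:
    """A structural connectome: symmetric non-negative weights, zero diagonal.

    Weights are in arbitrary streamline-count-like units. ``age`` (years) is
    optional and used by cohort-level analyses.
    """

    weights: np.ndarray
    region_labels: list[str]
    subject_id: str = ""
    age: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareMatrixError(f"weight matrix has shape {w.shape}; expected square")
        bad = np.argwhere(~np.isfinite(w))
        if bad.size:
            i, j = bad[0]
            raise NonFiniteWeightError(f"non-finite weight at cell ({i}, {j})")
        neg = np.argwhere(w < 0)
        if neg.size:
            i, j = neg[0]
            raise NegativeWeightError(f"negative weight {w[i, j]} at cell ({i}, {j})")
        dg = np.argwhere(np.abs(np.diag(w)) > 0)
        if dg.size:
            i = int(dg[0][0])
            raise NonzeroDiagonalError(f"nonzero diagonal entry {w[i, i]} at cell ({i}, {i})")
        asym = np.abs(w - w.T)
        if asym.max(initial=0.0) > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise AsymmetricMatrixError(
                f"asymmetry {asym[i, j]:.3g} at cell ({i}, {j}) exceeds tolerance {SYMMETRY_TOL}"
            )
        w = 0.5 * (w + w.T)  # remove sub-tolerance asymmetry
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if len(self.region_labels) != w.shape[0]:
            raise ConnectomeValidationError(
                f"{len(self.region_labels)} labels for {w.shape[0]} regions"
            )
        self.region_labels = [str(x) for x in self.region_labels]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def strength(self) -> np.ndarray:
        """Node strength: row sums of the weight matrix."""
        return self.weights.sum(axis=1)


@dataclass
class RegionTimeSeries:
    """T x M matrix of region signals sampled at a fixed period (seconds)."""

    values: np.ndarray
    sampling_period: float
    kind: str = "bold"  # one of firing_rate_Hz, gating, bold
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"time series must be 2-D (T x M); got shape {v.shape}")
        if v.shape[0] < 2:
            raise ValueError(f"need T >= 2 samples; got {v.shape[0]}")
        if not np.isfinite(v).all():
            raise ValueError("time series contains non-finite entries")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_period


@dataclass
class Cohort:
    """Connectomes plus ages and age-group labels (I1..I4)."""

    connectomes: list[Connectome]
    group_assignment: dict[str, str]
    ages: dict[str, float]

    def __post_init__(self) -> None:
        for sid, age in self.ages.items():
            if not 0.0 <= age <= 120.0:
                raise ValueError(f"age {age} of {sid} outside [0, 120]")
        for sid, grp in self.group_assignment.items():
            if grp not in GROUP_BANDS:
                raise ValueError(f"unknown group {grp!r} for {sid}")
            lo, hi = GROUP_BANDS[grp]
            age = self.ages.get(sid)
            if age is not None and not lo <= age <= hi:
                raise ValueError(f"{sid}: age {age} outside band {grp} = [{lo}, {hi}]")
        ms = {c.n_regions for c in self.connectomes}
        if len(ms) > 1:
            raise ValueError(f"mixed connectome sizes in cohort: {sorted(ms)}")

    def __len__(self) -> int:
        return len(self.connectomes)

    def subjects(self, group: str | None = None) -> list[Connectome]:
        if group is None:
            return list(self.connectomes)
        return [c for c in self.connectomes if self.group_assignment.get(c.subject_id) == group]

    def age_vector(self) -> np.ndarray:
        return np.array([self.ages[c.subject_id] for c in self.connectomes], dtype=float)


@dataclass
class RunConfig:
    """Configuration of a simulation + analysis run.

    ``bold_points * bold_tr`` defines the analysed BOLD duration (the full-
    scale default is 160 points at TR = 3 s, i.e. 8 minutes). ``burn_in`` is
    the haemodynamic settling time discarded before sampling BOLD, on top of
    ``dmf_burn_in`` seconds of neural transient discarded before the balloon
    stage.
    """

    M: int = 20
    G_grid: list[float] = field(default_factory=lambda: [round(1.0 + 0.1 * i, 1) for i in range(21)])
    n_runs_per_G: int = 112
    burn_in: float = 20.0
    dmf_burn_in: float = 10.0
    bold_tr: float = 3.0
    bold_points: int = 160
    order_range: tuple[int, int] = (3, 20)
    seed: int = 0
    sc_normalization: str = "max_to_cap"  # or "none"
    sc_cap: float = 0.2

    def __post_init__(self) -> None:
        n_min, n_max = self.order_range
        if n_min < 3:
            raise ValueError("minimum interaction order is 3")
        if n_max > self.M:
            raise ValueError(f"maximum order {n_max} exceeds region count {self.M}")
        if self.sc_normalization not in ("max_to_cap", "strength_to_cap", "none"):
            raise ValueError(f"unknown sc_normalization {self.sc_normalization!r}")

    @property
    def bold_duration(self) -> float:
        """Analysed BOLD duration in seconds (points x TR)."""
        return self.bold_points * self.bold_tr

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "order_range" in d:
            d["order_range"] = tuple(d["order_range"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["order_range"] = list(self.order_range)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


# ---------------------------------------------------------------------------
# connectome I/O


def _read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.rstrip("\n").split(sep)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t != "")
    if has_header:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        labels = [str(c) for c in df.columns]
        return df.to_numpy(dtype=float), labels
    df = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
    return df.to_numpy(dtype=float), None


def read_connectome(path: str | Path, subject_id: str = "", age: float | None = None) -> Connectome:
    """Read an M x M delimited-text weight matrix (optional label header)."""
    w, labels = _read_matrix(path)
    if labels is None:
        labels = [f"R{i + 1}" for i in range(w.shape[1])]
    if subject_id == "":
        subject_id = Path(path).stem
    return Connectome(weights=w, region_labels=labels, subject_id=subject_id, age=age)


def write_connectome(c: Connectome, path: str | Path) -> None:
    pd.DataFrame(c.weights, columns=c.region_labels).to_csv(path, index=False)


def normalize_sc(c: Connectome, mode: str = "max_to_cap", cap: float = 0.2) -> Connectome:
    """Rescale connectome weights.

    ``max_to_cap`` rescales so the largest entry equals ``cap`` (the common
    DMF convention, cap 0.2); ``strength_to_cap`` rescales so the largest
    node strength (row sum) equals ``cap``, which pins the quantity that
    actually bounds the recurrent coupling drive and so keeps a whole G sweep
    dynamically comparable across connectomes; ``none`` returns the input
    unchanged.
    """
    if mode == "none":
        return c
    if mode not in ("max_to_cap", "strength_to_cap"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if cap <= 0:
        raise ValueError("cap must be positive")
    mx = c.weights.max() if mode == "max_to_cap" else c.strength().max()
    if mx == 0:
        raise ValueError("cannot rescale an all-zero connectome (undefined scale)")
    return Connectome(
        weights=c.weights * (cap / mx),
        region_labels=list(c.region_labels),
        subject_id=c.subject_id,
        age=c.age,
    )


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject connectome CSVs plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cohort.connectomes:
        fname = f"{c.subject_id}.csv"
        write_connectome(c, out_dir / fname)
        rows.append(
            {
                "subject_id": c.subject_id,
                "age": cohort.ages[c.subject_id],
                "group": cohort.group_assignment[c.subject_id],
                "file": fname,
            }
        )
    manifest = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> Cohort:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    connectomes, groups, ages = [], {}, {}
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        ages[sid] = float(row.age)
        groups[sid] = str(row.group)
        connectomes.append(read_connectome(base / row.file, subject_id=sid, age=float(row.age)))
    return Cohort(connectomes=connectomes, group_assignment=groups, ages=ages)


def group_average_connectome(cohort: Cohort, group: str) -> Connectome:
    """Element-wise mean of the connectomes of one age group."""
    subs = cohort.subjects(group)
    if not subs:
        raise ValueError(f"no subjects in group {group!r}")
    w = np.mean([c.weights for c in subs], axis=0)
    return Connectome(
        weights=w,
        region_labels=list(subs[0].region_labels),
        subject_id=f"avg_{group}",
        age=float(np.mean([cohort.ages[c.subject_id] for c in subs])),
    )


# ---------------------------------------------------------------------------
# result tables and manifests


def write_results_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular records as CSV with a header (empty input -> header-only file)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(columns=["order", "group", "statistic", "p", "p_fdr", "significant"])
    df.to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_run_manifest(path: str | Path, config: RunConfig, seed: int, extra: dict | None = None) -> None:
    """JSON run manifest: configuration, master seed and package version."""
    from . import __version__

    d = dataclasses.asdict(config)
    d["order_range"] = list(config.order_range)
    manifest = {"config": d, "seed": int(seed), "package_version": __version__}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
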