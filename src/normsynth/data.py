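"""Core data model, CSV/JSON I/O, and the reproducible random-number contract.

A :class:`Sample` is an n x d matrix of finite reals in one of three named
representations: ``X`` (the original variables), ``Y`` (marginally normalized
via the monotone maps) or ``T`` (PCA-decorrelated).  All randomness in the
package flows through :func:`rng_stream`, which fans a single master seed out
into independent labeled substreams so that each pipeline stage is
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

REPRESENTATIONS = ("X", "Y", "T")


@dataclass
class Sample:
    """An n x d matrix of finite observations with named columns.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        Finite real observations, one row per observation.
    names : sequence of str
        Unique column labels, length d.
    rep : {"X", "Y", "T"}
        Which representation the values live in.
    """

    values: np.ndarray
    names: list[str]
    rep: str = "X"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValueError(f"need n >= 2 and d >= 1, got n={n}, d={d}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite entry at row {i}, column {j}")
        self.names = list(self.names)
        if len(self.names) != d:
            raise ValueError(f"{len(self.names)} names for {d} columns")
        if any(not str(nm) for nm in self.names):
            raise ValueError("empty column name")
        if len(set(self.names)) != d:
            raise ValueError("duplicate column names")
        if self.rep not in REPRESENTATIONS:
            raise ValueError(f"rep must be one of {REPRESENTATIONS}, got {self.rep!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def with_values(self, values: np.ndarray, rep: str | None = None) -> "Sample":
        return Sample(values, self.names, rep if rep is not None else self.rep)

    def digest(self) -> str:
        """SHA-256 of the raw bytes; provenance tag for archives."""
        h = hashlib.sha256()
        h.update(",".join(self.names).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()


@dataclass
class RunConfig:
    """Tunable sizes and levels for the whole pipeline.

    Defaults are the full-scale study conditions: a differential-evolution
    population of 1000 evolved for 30 generations per variable, 10^6 KDE
    augmentation draws and 10^6 normal draws per map, synthetic populations of
    10^6 rows, a 5% significance level, and 1000 evaluation repetitions /
    random projections.  Every count scales down for desk-scale runs.
    """

    seed: int = 0
    de_pop_size: int = 1000
    de_generations: int = 30
    kde_augment_n: int = 1_000_000
    map_normal_n: int = 1_000_000
    sp_size: int = 1_000_000
    alpha: float = 0.05
    n_eval_reps: int = 1000
    n_projections: int = 1000

    def __post_init__(self) -> None:
        for name in ("de_pop_size", "de_generations", "map_normal_n",
                     "sp_size", "n_eval_reps", "n_projections"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kde_augment_n < 0:
            raise ValueError("kde_augment_n must be nonnegative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def rng_stream(seed: int, label: str) -> np.random.Generator:
    """Independent reproducible generator for a (seed, label) pair.

    Identical pairs yield identical streams; distinct labels yield
    statistically independent streams (the label bytes extend the seed
    sequence entropy).
    """
    entropy = [int(seed) & 0xFFFFFFFF, *label.encode("utf-8")]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def read_sample(path: str | Path, rep: str = "X") -> Sample:
    """Read a header-row CSV into a :class:`Sample`.

    Every cell must be numeric and finite; the error message names the first
    offending cell (1-based data row, column label).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate header names in {path}: {dupes}")
    df = pd.read_csv(path, header=0, float_precision="round_trip")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(coerced)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"non-numeric cell at data row {i + 1}, column {col!r}: {df[col].iloc[i]!r}"
            )
        values[:, j] = coerced
    return Sample(values, [str(c) for c in header], rep)


def write_sample(sample: Sample, path: str | Path) -> Path:
    """Write a Sample as a header-row CSV at full (repr) precision.

    ``read_sample`` is an exact inverse: values survive bit-for-bit.
    """
    path = Path(path)
    pd.DataFrame(sample.values, columns=sample.names).to_csv(path, index=False)
    return path


@dataclass
class ModelArchive:
    """A fitted model: per-variable maps, the PCA of Y, and the run config.

    Serialized as a single JSON document so a fit can be reused without
    refitting (map knot tables embedded as paired arrays).
    """

    maps: list  # list[MarginalMap]
    pca: object  # PCAModel
    config: RunConfig
    names: list[str]
    provenance: str = ""
    de_results: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.maps) != self.pca.d or len(self.names) != self.pca.d:
            raise ValueError("maps, names and PCA dimension must agree")

    @property
    def d(self) -> int:
        return self.pca.d

    def to_json(self, path: str | Path) -> Path:
        from .mapping import MarginalMap  # local to avoid import cycle
        doc = {
            "names": self.names,
            "provenance": self.provenance,
            "config": self.config.to_dict(),
            "maps": [
                {"x_knots": m.x_knots.tolist(), "y_knots": m.y_knots.tolist(),
                 "meta": {k: v for k, v in m.meta.items()}}
                for m in self.maps
            ],
            "pca": {
                "P": self.pca.P.tolist(),
                "eigenvalues": self.pca.eigenvalues.tolist(),
                "means": self.pca.means.tolist(),
            },
            "bandwidths": [float(r.bandwidth) for r in self.de_results] or None,
        }
        path = Path(path)
        path.write_text(json.dumps(doc))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelArchive":
        from .mapping import MarginalMap
        from .pca import PCAModel
        doc = json.loads(Path(path).read_text())
        maps = [
            MarginalMap(np.asarray(m["x_knots"]), np.asarray(m["y_knots"]),
                        meta=dict(m.get("meta", {})))
            for m in doc["maps"]
        ]
        pca = PCAModel(
            P=np.asarray(doc["pca"]["P"]),
            eigenvalues=np.asarray(doc["pca"]["eigenvalues"]),
            means=np.asarray(doc["pca"]["means"]),
        )
        return cls(maps=maps, pca=pca, config=RunConfig.from_dict(doc["config"]),
                   names=list(doc["names"]), provenance=doc.get("provenance", ""))
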