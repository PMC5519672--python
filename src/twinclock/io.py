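"""Core containers and file I/O for the twin expression-clock pipeline.

All on-disk formats are plain text: probe-major TSV for expression matrices,
TSV for sample metadata and probe annotation, GMT for pathway membership,
YAML for pipeline configuration and JSON for stage outputs.  Readers are
strict: malformed input raises a diagnosed :class:`ValueError`, never a
silently truncated object.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Symbol assigned to probes without a gene annotation.  Probes carrying it
#: are excluded from extracted signatures.
UNKNOWN_SYMBOL = "unknown"


def substream(seed: int, stream: int) -> np.random.Generator:
    """Deterministic child RNG: one root seed, one integer stream key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {what} identifier(s): {dups[:10]}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe-by-sample expression matrix with optional gene-symbol annotation.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns
        (log2 intensities after preprocessing).
    annotation
        Maps probe id -> gene symbol.  Probes missing from the mapping, or
        mapped to an empty/NA entry, receive :data:`UNKNOWN_SYMBOL`.
    """

    values: pd.DataFrame
    annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        self.values = self.values.astype(float)
        ann = self.annotation
        if ann is None:
            ann = pd.Series(UNKNOWN_SYMBOL, index=self.values.index)
        else:
            ann = ann.reindex(self.values.index)
            ann = ann.replace("", np.nan).fillna(UNKNOWN_SYMBOL).astype(str)
        self.annotation = ann

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes: Iterable[str]) -> "ExpressionMatrix":
        probes = list(probes)
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise KeyError(f"probe(s) not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[probes], self.annotation.loc[probes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"sample(s) not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[samples], self.annotation)

    def design(self, probes: Sequence[str], samples: Sequence[str]) -> pd.DataFrame:
        """Samples-by-probes design block for regression."""
        return self.values.loc[list(probes), list(samples)].T


@dataclass
class TwinCohort:
    """Sample metadata binding samples into monozygotic couples.

    ``samples`` is indexed by sample id with columns ``couple_id`` (nullable
    for singleton cohorts), ``member`` (1 or 2 within a couple), ``age``
    (real years) and ``sex``.  Paired invariants — every couple appears
    exactly twice with member indices {1, 2} and concordant age and sex —
    are enforced at construction.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples.copy()
        _check_unique(df.index, "sample")
        required = {"age"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing column(s): {sorted(missing)}")
        df["age"] = df["age"].astype(float)
        if "couple_id" not in df.columns:
            df["couple_id"] = pd.NA
        if self._has_couples(df):
            self._validate_pairs(df)
        self.samples = df

    @staticmethod
    def _has_couples(df: pd.DataFrame) -> bool:
        return df["couple_id"].notna().any()

    @staticmethod
    def _validate_pairs(df: pd.DataFrame) -> None:
        if df["couple_id"].isna().any():
            bad = list(df.index[df["couple_id"].isna()])
            raise ValueError(f"samples without couple_id in a paired cohort: {bad[:10]}")
        if "member" not in df.columns:
            raise ValueError("paired cohort requires a 'member' column (1 or 2)")
        df["member"] = df["member"].astype(int)
        for cid, grp in df.groupby("couple_id", sort=False):
            if len(grp) != 2:
                raise ValueError(f"couple {cid!r} has {len(grp)} member(s), expected 2")
            if sorted(grp["member"]) != [1, 2]:
                raise ValueError(f"couple {cid!r} member indices must be {{1, 2}}")
            if grp["age"].nunique() != 1:
                raise ValueError(f"couple {cid!r} has discordant ages: {list(grp['age'])}")
            if "sex" in grp.columns and grp["sex"].nunique() != 1:
                raise ValueError(f"couple {cid!r} has discordant sex labels")

    @property
    def paired(self) -> bool:
        return self._has_couples(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def ages(self) -> pd.Series:
        return self.samples["age"]

    @property
    def n_couples(self) -> int:
        return self.samples["couple_id"].nunique() if self.paired else 0

    @property
    def couple_ids(self) -> list:
        if not self.paired:
            return []
        return list(pd.unique(self.samples["couple_id"]))

    def couple_members(self, couple_id) -> tuple[str, str]:
        grp = self.samples[self.samples["couple_id"] == couple_id].sort_values("member")
        if len(grp) != 2:
            raise KeyError(f"unknown couple {couple_id!r}")
        return tuple(grp.index)

    def iter_couples(self) -> Iterator[tuple[object, str, str]]:
        for cid in self.couple_ids:
            s1, s2 = self.couple_members(cid)
            yield cid, s1, s2

    def couple_age(self, couple_id) -> float:
        s1, _ = self.couple_members(couple_id)
        return float(self.samples.loc[s1, "age"])

    def drop_couples(self, couple_ids: Iterable) -> "TwinCohort":
        drop = set(couple_ids)
        keep = ~self.samples["couple_id"].isin(drop)
        return TwinCohort(self.samples[keep].copy())


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis.

    Defaults follow the published protocol: probes at least 2.5 SD below the
    mean divergence enter the signature, 1.5 SD for pathway enrichment,
    ridge parameter k = 1e-4, 100,000 random twin-split signatures, 10,000
    random validation signatures and 10,000 repeats of 10-fold CV.
    """

    z_threshold_signature: float = 2.5
    z_threshold_enrichment: float = 1.5
    ridge_k: float = 1e-4
    n_random_twin: int = 100_000
    n_random_validation: int = 10_000
    cv_folds: int = 10
    cv_repeats: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.z_threshold_signature > 0 and self.z_threshold_enrichment > 0):
            raise ValueError("z thresholds must be > 0")
        if self.ridge_k < 0:
            raise ValueError("ridge_k must be >= 0")
        for name in ("n_random_twin", "n_random_validation", "cv_folds", "cv_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------


def read_annotation(path) -> pd.Series:
    """Read a two-column TSV (header ``probe_id<TAB>symbol``) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation file {path} needs two columns (probe_id, symbol)")
    _check_unique(df.iloc[:, 0], "annotation probe")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="symbol")


def read_expression(path, annotation_path=None, transpose: bool = False) -> ExpressionMatrix:
    """Read a probe-major TSV expression matrix.

    First column holds probe ids, the header row holds sample ids.  With
    ``transpose=True`` the file is sample-major and is transposed after
    reading.  Any non-numeric cell is a hard error reporting its location.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        raw = raw.T
    _check_unique(raw.index, "probe")
    _check_unique(raw.columns, "sample")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        cells = [
            f"(probe={raw.index[r]!r}, sample={raw.columns[c]!r}, value={raw.iat[r, c]!r})"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValueError(f"non-numeric expression cell(s): {', '.join(cells)}")
    annotation = read_annotation(annotation_path) if annotation_path else None
    return ExpressionMatrix(numeric, annotation)


def write_expression(matrix: ExpressionMatrix, path, annotation_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")
    if annotation_path:
        matrix.annotation.rename("symbol").to_csv(
            annotation_path, sep="\t", index_label="probe_id"
        )


def read_metadata(path) -> TwinCohort:
    """Read sample metadata TSV into a validated :class:`TwinCohort`.

    Expected columns: ``sample_id``, ``age`` and, for paired cohorts,
    ``couple_id``/``member``/``sex``.  Singleton cohorts may omit the couple
    columns entirely; paired invariants are then skipped.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("metadata requires a 'sample_id' column")
    df = df.set_index("sample_id")
    return TwinCohort(df)


def write_metadata(cohort: TwinCohort, path) -> None:
    cohort.samples.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT pathway files
# ---------------------------------------------------------------------------


def read_gmt(path):
    """Read a GMT file into a :class:`~twinclock.enrichment.PathwayAnnotation`.

    Each line: pathway id, description, then tab-separated member ids.
    Duplicate members within a line are deduplicated; empty pathways are
    retained with a warning.  Members absent from a given analysis background
    are dropped at analysis time, not here.
    """
    from .enrichment import PathwayAnnotation

    pathways: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs id and description")
            pid, desc, *members = parts
            if pid in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            members = frozenset(m for m in members if m)
            if not members:
                log.warning("pathway %r has no members", pid)
            pathways[pid] = members
            names[pid] = desc
            n_lines += 1
    if n_lines == 0:
        log.warning("GMT file %s is empty", path)
    return PathwayAnnotation(pathways=pathways, names=names)


def write_gmt(annotation, path) -> None:
    with open(path, "w") as fh:
        for pid, members in annotation.pathways.items():
            desc = annotation.names.get(pid, pid)
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# signature / JSON exchange
# ---------------------------------------------------------------------------


def write_signature(signature, path) -> None:
    """Signature exchange format: JSON list of {probe_id, gene_symbol, coefficient}."""
    model = signature.model
    coef = {}
    if model is not None:
        coef = dict(zip(model.probes, model.coefficients))
    records = [
        {
            "probe_id": p,
            "gene_symbol": s,
            "coefficient": float(coef[p]) if p in coef else None,
        }
        for p, s in zip(signature.probes, signature.symbols)
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def read_signature(path):
    from .signature import RidgeModel, Signature

    with open(path) as fh:
        records = json.load(fh)
    probes = [r["probe_id"] for r in records]
    symbols = [r["gene_symbol"] for r in records]
    coefs = [r.get("coefficient") for r in records]
    model = None
    if all(c is not None for c in coefs) and probes:
        model = RidgeModel(
            probes=probes,
            coefficients=np.asarray(coefs, float),
            intercept=0.0,
            k=float("nan"),
            center=np.zeros(len(probes)),
            scale=np.ones(len(probes)),
        )
    return Signature(probes=probes, symbols=symbols, model=model, provenance={})


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
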