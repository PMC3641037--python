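"""Readers, writers and validated containers for the pipeline's file formats.

All tabular formats are tab-separated UTF-8 with a header row.  Alignments are
plain FASTA.  Flagged individual pairs can be exported as RFC 7946 GeoJSON
(LineString per pair, WGS84 longitude-latitude order).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "MISSING",
    "BinaryMarkerMatrix",
    "SampleTable",
    "CodingAlignment",
    "EnvTable",
    "load_dataset",
    "write_table",
    "write_geojson_pairs",
]

#: sentinel used in the integer marker matrix for missing band calls
MISSING = -1

#: TSV token for a missing marker cell
MISSING_TOKEN = "?"

_FLOAT_FMT = "%.6g"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class BinaryMarkerMatrix:
    """Individuals x loci band presence/absence matrix.

    ``values`` holds 0/1 with :data:`MISSING` (-1) for missing calls.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        _check_unique(self.individual_ids, "individual ids")
        _check_unique(self.locus_ids, "locus ids")
        n, L = self.values.shape
        if n != len(self.individual_ids) or L != len(self.locus_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary marker cell at individual {self.individual_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def observed_mask(self) -> np.ndarray:
        return self.values != MISSING

    def drop_monomorphic(self) -> tuple["BinaryMarkerMatrix", list[str]]:
        """Return a copy without loci that are invariant among observed calls."""
        obs = self.observed_mask()
        vals = np.where(obs, self.values, 0)
        ones = (vals * obs).sum(axis=0)
        total = obs.sum(axis=0)
        poly = (ones > 0) & (ones < total)
        dropped = [l for l, keep in zip(self.locus_ids, poly) if not keep]
        kept = BinaryMarkerMatrix(
            self.individual_ids,
            [l for l, keep in zip(self.locus_ids, poly) if keep],
            self.values[:, poly],
        )
        return kept, dropped

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.locus_ids
        )
        df.index.name = "individual_id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().astype(object)
        df = df.where(df != MISSING, MISSING_TOKEN)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinaryMarkerMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        vals = np.empty(df.shape, dtype=np.int8)
        raw = df.to_numpy()
        for (i, j), cell in np.ndenumerate(raw):
            cell = str(cell).strip()
            if cell == MISSING_TOKEN:
                vals[i, j] = MISSING
            elif cell in ("0", "1"):
                vals[i, j] = int(cell)
            else:
                raise ValueError(
                    f"non-binary marker cell at individual {df.index[i]!r}, "
                    f"locus {df.columns[j]!r}: {cell!r}"
                )
        return cls(list(df.index), list(df.columns), vals)


@dataclass
class SampleTable:
    """Per-individual metadata: locality, WGS84 coordinates, optional labels."""

    data: pd.DataFrame

    REQUIRED = ("individual_id", "locality_id", "latitude", "longitude")

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df["individual_id"] = df["individual_id"].astype(str)
        df["locality_id"] = df["locality_id"].astype(str)
        df["latitude"] = df["latitude"].astype(float)
        df["longitude"] = df["longitude"].astype(float)
        _check_unique(df["individual_id"].tolist(), "individual ids")
        if (df["latitude"].abs() > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        if (df["longitude"].abs() > 180).any():
            raise ValueError("longitude outside [-180, 180]")
        self.data = df.reset_index(drop=True)

    @property
    def individual_ids(self) -> list[str]:
        return self.data["individual_id"].tolist()

    def subset(self, ids: Iterable[str]) -> "SampleTable":
        ids = list(ids)
        df = self.data.set_index("individual_id").loc[ids].reset_index()
        return SampleTable(df)

    def coordinates(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """(n, 2) array of (latitude, longitude)."""
        df = self.data.set_index("individual_id")
        if ids is not None:
            df = df.loc[list(ids)]
        return df[["latitude", "longitude"]].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"individual_id": str, "locality_id": str}))


_VALID_BASES = frozenset(b"ACGT-N")


@dataclass
class CodingAlignment:
    """Gapped alignment of a protein-coding locus with in/outgroup flags."""

    sequence_ids: list[str]
    sequences: np.ndarray  # (n, L) array of dtype 'S1', upper case
    frame_offset: int = 0
    is_outgroup: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sequence_ids = [str(s) for s in self.sequence_ids]
        _check_unique(self.sequence_ids, "sequence ids")
        seqs = np.asarray(self.sequences, dtype="S1")
        seqs = np.char.upper(seqs)
        if seqs.ndim != 2 or seqs.shape[0] != len(self.sequence_ids):
            raise ValueError("sequence matrix shape does not match ids")
        bad = set(np.unique(seqs).tolist()) - {bytes([b]) for b in _VALID_BASES}
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        self.sequences = seqs
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.is_outgroup is None:
            self.is_outgroup = np.zeros(len(self.sequence_ids), dtype=bool)
        self.is_outgroup = np.asarray(self.is_outgroup, dtype=bool)
        if self.is_outgroup.shape != (len(self.sequence_ids),):
            raise ValueError("is_outgroup length mismatch")

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    def ingroup(self) -> "CodingAlignment":
        keep = ~self.is_outgroup
        return CodingAlignment(
            [s for s, k in zip(self.sequence_ids, keep) if k],
            self.sequences[keep],
            self.frame_offset,
            np.zeros(int(keep.sum()), dtype=bool),
        )

    def as_strings(self) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.sequences]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq, out in zip(
                self.sequence_ids, self.as_strings(), self.is_outgroup
            ):
                tag = " outgroup" if out else ""
                fh.write(f">{sid}{tag}\n{seq}\n")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        frame_offset: int = 0,
        outgroup_ids: Iterable[str] | None = None,
    ) -> "CodingAlignment":
        ids, rows, flags = [], [], []
        outset = set(outgroup_ids or ())
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(np.frombuffer(str(rec.seq).upper().encode(), dtype="S1"))
            flags.append(rec.id in outset or "outgroup" in rec.description.split())
        if not ids:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
        return cls(ids, np.vstack(rows), frame_offset, np.array(flags))


@dataclass
class EnvTable:
    """Environmental variables per locality (columns = variables)."""

    data: pd.DataFrame  # index = locality_id

    def __post_init__(self) -> None:
        df = self.data.copy()
        if df.index.name != "locality_id":
            if "locality_id" in df.columns:
                df = df.set_index("locality_id")
            else:
                raise ValueError("env table needs a locality_id column or index")
        df.index = df.index.astype(str)
        _check_unique(df.index.tolist(), "locality ids")
        df = df.astype(float)
        if not np.isfinite(df.to_numpy()).all():
            raise ValueError("env table contains non-finite values")
        self.data = df

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def for_samples(self, samples: SampleTable) -> pd.DataFrame:
        """Env rows aligned to individuals; localities without data yield NaN rows."""
        loc = samples.data.set_index("individual_id")["locality_id"]
        out = self.data.reindex(loc.to_numpy())
        out.index = loc.index
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnvTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def load_dataset(
    markers_path: str | Path,
    metadata_path: str | Path,
    fasta_path: str | Path | None = None,
    env_path: str | Path | None = None,
):
    """Load and cross-validate the standard input bundle.

    Returns ``(markers, samples, alignment_or_None, env_or_None)``.  Every
    marker row must have metadata; individuals whose locality lacks an
    environment row are warned about (they are excluded later by the scan).
    """
    markers = BinaryMarkerMatrix.from_tsv(markers_path)
    samples = SampleTable.from_tsv(metadata_path)
    known = set(samples.individual_ids)
    orphans = [i for i in markers.individual_ids if i not in known]
    if orphans:
        raise ValueError(f"marker individuals missing from metadata: {orphans}")
    alignment = CodingAlignment.from_fasta(fasta_path) if fasta_path else None
    env = None
    if env_path:
        env = EnvTable.from_tsv(env_path)
        have = set(env.data.index)
        missing_loc = sorted(
            set(samples.data["locality_id"]) - have
        )
        if missing_loc:
            warnings.warn(
                f"{len(missing_loc)} localities lack environmental data and will be "
                f"excluded from the association scan: {missing_loc[:10]}"
            )
    return markers, samples, alignment, env


def write_table(result, path: str | Path) -> None:
    """Write any result exposing ``to_frame()`` (or a DataFrame) as TSV."""
    if hasattr(result, "to_frame"):
        df = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        df = result
    else:
        raise TypeError(f"cannot serialise {type(result).__name__} as a table")
    df.to_csv(path, sep="\t", index=df.index.name is not None, float_format=_FLOAT_FMT)


def write_geojson_pairs(pairs, samples: SampleTable, path: str | Path) -> None:
    """Export flagged pairs as a GeoJSON FeatureCollection of LineStrings.

    Coordinates follow RFC 7946 (longitude, latitude) order.
    """
    coords = samples.data.set_index("individual_id")[["longitude", "latitude"]]
    features = []
    for row in pairs.pairs.itertuples(index=False):
        for sid in (row.id_a, row.id_b):
            if sid not in coords.index:
                raise ValueError(f"pair individual {sid!r} absent from sample table")
        a = coords.loc[row.id_a]
        b = coords.loc[row.id_b]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [float(a["longitude"]), float(a["latitude"])],
                        [float(b["longitude"]), float(b["latitude"])],
                    ],
                },
                "properties": {
                    "id_a": row.id_a,
                    "id_b": row.id_b,
                    "genetic_distance": float(row.d_gen),
                    "geographic_distance": float(row.d_geo),
                    "mode": pairs.mode,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
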