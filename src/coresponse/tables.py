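"""OTU tables, taxonomy and sample-design handling.

The central container is :class:`OtuTable`, a thin validated wrapper around a
pandas DataFrame (rows = OTUs, columns = samples).  Taxonomy is a per-OTU
ranked lineage (kingdom through genus), and the sample design maps each
sample to its soil compartment (bulk soil ``BS`` or a rhizosphere ``SRz`` /
``TRz``), irrigation treatment (full ``FI`` or deficit ``DI``) and replicate
index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
COMPARTMENTS = ("BS", "SRz", "TRz")
TREATMENTS = ("FI", "DI")
UNASSIGNED = "unassigned"

__all__ = [
    "OtuTable",
    "Lineage",
    "TaxonomyMap",
    "SampleDesign",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_design",
    "write_design",
    "to_relative",
    "filter_prevalence",
]


class FormatError(ValueError):
    """Malformed input file (duplicate identifiers, bad header, ...)."""


class DegenerateInputError(ValueError):
    """Input that makes the requested computation undefined."""


@dataclass(frozen=True)
class OtuTable:
    """Abundance matrix with OTU rows and sample columns.

    Parameters
    ----------
    data:
        DataFrame with OTU identifiers as the index and sample identifiers
        as columns.  Values must be non-negative and finite.
    value_kind:
        ``"counts"`` for read counts, ``"relative"`` for per-sample
        proportions (each column sums to 1).
    """

    data: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "relative"):
            raise ValueError(f"value_kind must be 'counts' or 'relative', got {self.value_kind!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate OTU ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if values.size and (not np.all(np.isfinite(values)) or (values < 0).any()):
            raise ValueError("abundance values must be finite and non-negative")
        if self.value_kind == "relative" and values.size:
            colsums = values.sum(axis=0)
            # Row subsets of a normalized table stay "relative"; columns may
            # then sum to less than 1, but never more, and never to 0.
            if (colsums > 1.0 + 1e-9).any() or (colsums <= 0).any():
                raise ValueError("relative-abundance columns must sum to at most 1 and not be all-zero")

    @property
    def otu_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return OtuTable(self.data.loc[:, list(sample_ids)].copy(), self.value_kind)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.data.index]
        if missing:
            raise KeyError(f"OTUs not in table: {missing}")
        return OtuTable(self.data.loc[list(otu_ids)].copy(), self.value_kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.value_kind == other.value_kind and self.data.equals(other.data)


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic lineage; missing ranks are ``"unassigned"``."""

    kingdom: str = UNASSIGNED
    phylum: str = UNASSIGNED
    klass: str = UNASSIGNED
    order: str = UNASSIGNED
    family: str = UNASSIGNED
    genus: str = UNASSIGNED

    def at_rank(self, rank: str) -> str:
        key = "klass" if rank == "class" else rank
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, key)

    def prefix(self, rank: str) -> tuple[str, ...]:
        """Lineage truncated at `rank`, used as an aggregation key."""
        stop = RANKS.index(rank) + 1
        return tuple(self.at_rank(r) for r in RANKS[:stop])


_PREFIXES = {"k": "kingdom", "d": "kingdom", "p": "phylum", "c": "klass",
             "o": "order", "f": "family", "g": "genus"}


def parse_lineage(text: str) -> Lineage:
    """Parse a lineage string.

    Accepts both QIIME-style ``k__Bacteria;p__Firmicutes;...`` (``d__`` for
    domain is treated as kingdom) and plain semicolon-delimited rank lists.
    Empty or missing ranks become ``"unassigned"``; kingdoms other than
    Bacteria and Fungi are normalized to ``"other"``.
    """
    fields = dict.fromkeys(["kingdom", "phylum", "klass", "order", "family", "genus"], UNASSIGNED)
    parts = [p.strip() for p in str(text).split(";")]
    prefixed = any(len(p) > 2 and p[1:3] == "__" for p in parts if p)
    if prefixed:
        for part in parts:
            if len(part) > 2 and part[1:3] == "__":
                key = _PREFIXES.get(part[0].lower())
                name = part[3:].strip()
                if key and name:
                    fields[key] = name
    else:
        keys = ["kingdom", "phylum", "klass", "order", "family", "genus"]
        for key, part in zip(keys, parts):
            if part:
                fields[key] = part
    if fields["kingdom"] not in ("Bacteria", "Fungi"):
        fields["kingdom"] = "other" if fields["kingdom"] != UNASSIGNED else UNASSIGNED
        if fields["kingdom"] == UNASSIGNED:
            fields["kingdom"] = "other"
    return Lineage(**fields)


class TaxonomyMap:
    """Mapping from OTU id to ranked lineage."""

    def __init__(self, lineages: Mapping[str, Lineage]):
        self._lineages = dict(lineages)

    def __len__(self) -> int:
        return len(self._lineages)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._lineages

    def __getitem__(self, otu_id: str) -> Lineage:
        try:
            return self._lineages[otu_id]
        except KeyError:
            raise KeyError(f"OTU {otu_id!r} has no taxonomy assignment") from None

    def kingdom(self, otu_id: str) -> str:
        return self[otu_id].kingdom

    def items(self):
        return self._lineages.items()

    @classmethod
    def from_strings(cls, strings: Mapping[str, str]) -> "TaxonomyMap":
        return cls({otu: parse_lineage(s) for otu, s in strings.items()})


class SampleDesign:
    """Sample metadata: compartment, treatment and replicate per sample.

    The (compartment, treatment, replicate) triples must be unique; the
    study layout is three replicates per compartment x treatment cell.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"compartment", "treatment", "replicate"}
        if not required.issubset(frame.columns):
            raise FormatError(f"design needs columns {sorted(required)}")
        frame = frame.copy()
        frame["replicate"] = frame["replicate"].astype(int)
        if frame.index.duplicated().any():
            raise FormatError("duplicate sample ids in design")
        bad_t = set(frame["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValueError(f"unknown treatments {sorted(bad_t)}; expected {TREATMENTS}")
        if (frame["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")
        triples = frame[["compartment", "treatment", "replicate"]]
        if triples.duplicated().any():
            raise FormatError("(compartment, treatment, replicate) triples must be unique")
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self._frame.index]

    @property
    def compartments(self) -> list[str]:
        return sorted(set(self._frame["compartment"]))

    def samples(self, compartment: str | None = None, treatment: str | None = None) -> list[str]:
        """Sample ids for a compartment/treatment cell, ordered by replicate."""
        sel = self._frame
        if compartment is not None:
            sel = sel[sel["compartment"] == compartment]
        if treatment is not None:
            sel = sel[sel["treatment"] == treatment]
        sel = sel.sort_values(["treatment", "replicate"])
        return [str(i) for i in sel.index]

    def replicate_of(self, sample_id: str) -> int:
        return int(self._frame.loc[sample_id, "replicate"])

    def group_label(self, sample_id: str) -> str:
        row = self._frame.loc[sample_id]
        return f"{row['compartment']}-{row['treatment']}"


# ---------------------------------------------------------------------------
# Readers / writers


def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU abundance table from TSV or BIOM-JSON.

    TSV dialect: UTF-8, tab separated, first column OTU ids (the header cell
    may be ``#OTU ID`` or anything else), remaining columns one per sample.
    BIOM-JSON: the minimal dense/sparse JSON layout.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            dups = sorted({s for s in samples if samples.count(s) > 1})
            raise FormatError(f"duplicate sample ids in header: {dups}")
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        try:
            frame = frame.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric abundance cell in {path}: {exc}") from exc
    elif format == "biom-json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        otu_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        shape = (len(otu_ids), len(sample_ids))
        values = np.zeros(shape)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                values[int(i), int(j)] = v
        else:
            values[:] = np.asarray(doc["data"], dtype=float)
        frame = pd.DataFrame(values, index=otu_ids, columns=sample_ids)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom-json'")
    colsums = frame.to_numpy(dtype=float).sum(axis=0) if frame.size else np.array([])
    if frame.size and (colsums == 0).any():
        zero_cols = [c for c, s in zip(frame.columns, colsums) if s == 0]
        warnings.warn(f"samples with zero total abundance: {zero_cols}", stacklevel=2)
    return OtuTable(frame, value_kind="counts")


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.data.copy()
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": list(table.shape),
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.values().tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of ``otu_id<TAB>lineage string``."""
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[1] < 2:
        raise FormatError("taxonomy TSV needs at least two columns (otu_id, lineage)")
    ids = frame.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise FormatError("duplicate OTU ids in taxonomy")
    return TaxonomyMap.from_strings(dict(zip(ids, frame.iloc[:, 1].astype(str))))


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    rows = []
    for otu, lin in taxonomy.items():
        text = ";".join(f"{r[0]}__{lin.at_rank(r)}" for r in RANKS)
        rows.append((otu, text))
    pd.DataFrame(rows, columns=["otu_id", "lineage"]).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    return SampleDesign(frame)


def write_design(design: SampleDesign, path: str | Path) -> None:
    out = design.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transformations


def to_relative(table: OtuTable) -> OtuTable:
    """Convert a counts table to relative abundances (columns sum to 1)."""
    if table.value_kind != "counts":
        raise ValueError("to_relative expects a counts table")
    values = table.values()
    colsums = values.sum(axis=0)
    if (colsums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, colsums) if t <= 0]
        raise DegenerateInputError(f"cannot normalize zero-sum samples: {bad}")
    frame = pd.DataFrame(values / colsums, index=table.data.index, columns=table.data.columns)
    return OtuTable(frame, value_kind="relative")


def filter_prevalence(
    table: OtuTable,
    design: SampleDesign,
    group_by: str = "compartment",
    min_present: int = 4,
    compartment: str | None = None,
) -> dict[str, OtuTable]:
    """Prevalence-filter OTUs within sample groups.

    ``group_by="compartment"`` implements the network-stage rule (an OTU must
    be non-zero in at least `min_present` of the compartment's six samples);
    ``group_by="compartment_treatment"`` the community rule (at least
    `min_present` of a treatment cell's three samples; an OTU is kept for the
    compartment if it passes in either treatment cell).

    Returns a mapping from compartment to the filtered table restricted to
    that compartment's samples.
    """
    if group_by not in ("compartment", "compartment_treatment"):
        raise ValueError("group_by must be 'compartment' or 'compartment_treatment'")
    compartments = [compartment] if compartment is not None else design.compartments
    out: dict[str, OtuTable] = {}
    for comp in compartments:
        samples = design.samples(comp)
        samples = [s for s in samples if s in table.data.columns]
        if not samples:
            warnings.warn(f"no samples of compartment {comp} in table", stacklevel=2)
            continue
        sub = table.data.loc[:, samples]
        if group_by == "compartment":
            if min_present > len(samples):
                raise ValueError(f"min_present={min_present} exceeds group size {len(samples)}")
            keep = (sub > 0).sum(axis=1) >= min_present
        else:
            keep = pd.Series(False, index=sub.index)
            for trt in TREATMENTS:
                cell = [s for s in design.samples(comp, trt) if s in sub.columns]
                if not cell:
                    continue
                if min_present > len(cell):
                    raise ValueError(f"min_present={min_present} exceeds cell size {len(cell)}")
                keep |= (sub[cell] > 0).sum(axis=1) >= min_present
        if not keep.any():
            warnings.warn(f"prevalence filter removed every OTU for {comp}", stacklevel=2)
        out[comp] = OtuTable(sub.loc[keep].copy(), table.value_kind)
    return out
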