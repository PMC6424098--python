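"""Table I/O: intensity tables, reference sets, complex catalogs, results.

All on-disk formats are plain text: FASTA for the parent protein, TSV for
designs, intensities, reference sets, regions and results, and a CORUM-style
TSV for complex catalogs. Intensity tables come in two dialects: a generic
``uniprot_id / gene_name / <spot columns>`` TSV and a read-only MaxQuant
proteinGroups dialect (``Majority protein IDs``, ``Intensity <spot>`` columns,
contaminant/decoy flags).

Identifier normalization: UniProt isoform suffixes (``-<digits>``) are
stripped everywhere, and rows sharing a normalized id are merged by per-spot
maximum (summing would double-count peptides shared between isoforms).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from prisma_screen.matrix_design import ProteinSequence, TilingPeptide

logger = logging.getLogger(__name__)

_ISOFORM_RE = re.compile(r"-\d+$")


def normalize_uniprot_id(uid: str) -> str:
    """Strip a UniProt isoform suffix (``P12345-2`` -> ``P12345``)."""
    return _ISOFORM_RE.sub("", uid.strip())


@dataclass
class IntensityTable:
    """Protein x spot intensity matrix for one replicate.

    ``values`` is indexed by uniprot_id with one column per spot, aligned to
    the design's spot order; 0 means not detected. ``gene_names`` maps
    uniprot_id -> gene name (may be empty strings).
    """

    replicate_id: str
    values: pd.DataFrame
    gene_names: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein rows; run merge_protein_ids first")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def spots(self) -> list[str]:
        return list(self.values.columns)

    def detected_proteins(self) -> set[str]:
        """Proteins with at least one nonzero spot."""
        mask = (self.values.to_numpy() > 0).any(axis=1)
        return set(self.values.index[mask])


@dataclass(frozen=True)
class ReferenceSet:
    """A named set of interactor identifiers (reference interactome or IP hits)."""

    name: str
    members: frozenset[str]
    role: str = "reference_interactome"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"reference set {self.name!r} is empty")
        if self.role not in ("reference_interactome", "ip_dataset"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ComplexCatalog:
    """CORUM-style catalog: complexes with UniProt member sets."""

    complexes: list[tuple[str, str, frozenset[str]]]  # (complex_id, name, members)

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.complexes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate complex_id in catalog")

    @property
    def background(self) -> frozenset[str]:
        out: set[str] = set()
        for _, _, members in self.complexes:
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.complexes)


def read_protein_fasta(path: str | Path) -> ProteinSequence:
    """First record of a FASTA file as a :class:`ProteinSequence`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return ProteinSequence(rec.id, str(rec.seq).upper())


def read_intensity_table(
    path: str | Path,
    design: Sequence[TilingPeptide],
    dialect: str = "generic_tsv",
    replicate_id: str | None = None,
    strict: bool = True,
) -> IntensityTable:
    """Read one replicate's protein x spot intensity TSV.

    ``generic_tsv`` expects columns ``uniprot_id``, ``gene_name`` and one
    column per spot_id. The ``maxquant_protein_groups`` dialect reads
    ``Majority protein IDs`` (first entry as the id), ``Gene names`` and
    ``Intensity <spot_id>`` columns, dropping contaminant/reverse-decoy rows
    (``CON__``/``REV__`` prefixes or ``+`` in the flag columns).

    Spot columns are aligned to the design order; spots missing from the file
    are filled with 0 (warned). Unknown spot columns raise under ``strict``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect not in ("generic_tsv", "maxquant_protein_groups"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    spot_ids = [t.spot_id for t in design]

    if dialect == "generic_tsv":
        if "uniprot_id" not in frame.columns:
            raise ValueError(f"{path}: missing required column 'uniprot_id'")
        ids = frame["uniprot_id"].astype(str)
        genes = frame.get("gene_name", pd.Series([""] * len(frame))).fillna("")
        spot_cols = [c for c in frame.columns if c not in ("uniprot_id", "gene_name")]
        col_of = {c: c for c in spot_cols}
    else:
        id_col = next(
            (c for c in ("Majority protein IDs", "Protein IDs") if c in frame.columns),
            None,
        )
        if id_col is None:
            raise ValueError(f"{path}: missing 'Majority protein IDs' column")
        drop = pd.Series(False, index=frame.index)
        for flag_col in ("Reverse", "Potential contaminant", "Contaminant"):
            if flag_col in frame.columns:
                drop |= frame[flag_col].fillna("") == "+"
        first_id = frame[id_col].astype(str).str.split(";").str[0]
        drop |= first_id.str.startswith(("CON__", "REV__"))
        n_dropped = int(drop.sum())
        if n_dropped:
            logger.info("%s: dropped %d contaminant/decoy rows", path, n_dropped)
        frame = frame.loc[~drop]
        ids = frame[id_col].astype(str).str.split(";").str[0]
        genes = (
            frame.get("Gene names", pd.Series([""] * len(frame), index=frame.index))
            .fillna("")
            .astype(str)
            .str.split(";")
            .str[0]
        )
        spot_cols = [c for c in frame.columns if c.startswith("Intensity ")]
        col_of = {c: c[len("Intensity ") :] for c in spot_cols}

    unknown = [c for c in spot_cols if col_of[c] not in set(spot_ids)]
    if unknown and strict:
        raise ValueError(f"{path}: spot columns not in design: {unknown}")
    values = pd.DataFrame(0.0, index=range(len(frame)), columns=spot_ids)
    missing = []
    present = {col_of[c]: c for c in spot_cols if col_of[c] in set(spot_ids)}
    for sid in spot_ids:
        if sid in present:
            col = pd.to_numeric(frame[present[sid]], errors="coerce")
            if col.isna().any():
                row = int(col.index[col.isna()][0])
                raise ValueError(
                    f"{path}: non-numeric intensity in column {present[sid]!r}, "
                    f"row {row}"
                )
            values[sid] = col.to_numpy(dtype=float)
        else:
            missing.append(sid)
    if missing:
        logger.warning("%s: %d design spots missing, filled with 0", path, len(missing))
    values.index = pd.Index(ids.to_numpy(), name="uniprot_id")
    gene_names = pd.Series(genes.to_numpy(), index=values.index, name="gene_name")
    table = IntensityTable(
        replicate_id=replicate_id or path.stem,
        values=values,
        gene_names=gene_names,
    )
    return merge_protein_ids(table)


def merge_protein_ids(table: IntensityTable) -> IntensityTable:
    """Normalize isoform ids and merge duplicate rows by per-spot maximum.

    The merged row's gene name is taken from the input row with the highest
    total intensity. Idempotent; never decreases any per-spot value.
    """
    norm = table.values.index.map(normalize_uniprot_id)
    if not norm.has_duplicates and (norm == table.values.index).all():
        return table
    values = table.values.copy()
    values.index = pd.Index(norm, name="uniprot_id")
    totals = values.sum(axis=1)
    merged = values.groupby(level=0, sort=True).max()
    # gene name from the highest-total-intensity contributing row
    gene_frame = pd.DataFrame(
        {"gene": table.gene_names.to_numpy(), "total": totals.to_numpy()},
        index=values.index,
    )
    best = gene_frame.sort_values("total", kind="stable").groupby(level=0).last()
    gene_names = best["gene"].reindex(merged.index).rename("gene_name")
    return IntensityTable(table.replicate_id, merged, gene_names)


def read_complex_catalog(
    path: str | Path, organism_filter: str = "human_only"
) -> ComplexCatalog:
    """Read a CORUM-format TSV (complex id, name, organism, ``;``-separated
    subunit UniProt ids). Non-human rows are removed under ``human_only``;
    complexes with identical member sets are deduplicated keeping the lowest
    complex_id; member ids are isoform-normalized.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().replace(" ", "").replace("_", ""): c for c in frame.columns}

    def find(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"{path}: none of the columns {names} found")

    id_col = find("complexid")
    name_col = find("complexname", "name")
    org_col = find("organism")
    mem_col = find("subunitsuniprotids", "subunits(uniprotids)", "members")

    parsed: list[tuple[str, str, frozenset[str]]] = []
    for _, row in frame.iterrows():
        if organism_filter == "human_only" and str(row[org_col]).strip().lower() not in (
            "human",
            "homo sapiens",
        ):
            continue
        raw = row[mem_col]
        members = frozenset(
            normalize_uniprot_id(m)
            for m in str(raw).split(";")
            if not pd.isna(raw) and m.strip()
        )
        if not members:
            logger.warning("%s: complex %s has no members, skipped", path, row[id_col])
            continue
        parsed.append((str(row[id_col]), str(row[name_col]), members))

    def sort_key(cid: str):
        return (0, int(cid)) if cid.isdigit() else (1, cid)

    deduped: dict[frozenset[str], tuple[str, str, frozenset[str]]] = {}
    for cid, name, members in parsed:
        kept = deduped.get(members)
        if kept is None or sort_key(cid) < sort_key(kept[0]):
            deduped[members] = (cid, name, members)
    out = sorted(deduped.values(), key=lambda c: sort_key(c[0]))
    return ComplexCatalog(out)


def read_reference_set(
    path: str | Path, name: str, role: str = "reference_interactome"
) -> ReferenceSet:
    """Read an interactor id list: one id per line, or a TSV with a
    ``uniprot_id`` column. Ids are isoform-normalized and deduplicated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty reference set file")
    first = text.splitlines()[0]
    if "\t" in first or first.strip() == "uniprot_id":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if "uniprot_id" not in frame.columns:
            raise ValueError(f"{path}: missing 'uniprot_id' column")
        raw = frame["uniprot_id"].dropna().astype(str)
    else:
        raw = pd.Series(text.splitlines())
    members = frozenset(normalize_uniprot_id(m) for m in raw if m.strip())
    return ReferenceSet(name=name, members=members, role=role)


def intensity_table_to_frame(table: IntensityTable) -> pd.DataFrame:
    """Generic-TSV layout of an intensity table (round-trips through
    :func:`read_intensity_table` with the ``generic_tsv`` dialect)."""
    frame = table.values.reset_index()
    frame.insert(1, "gene_name", table.gene_names.to_numpy())
    return frame


def write_results(
    bundle: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write each named DataFrame as a sorted TSV plus a ``manifest.json``.

    Rows are sorted by the first column, columns kept in given order, so two
    runs with identical inputs produce byte-identical files. The manifest
    records each file's sha256 along with the config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(bundle):
        frame = bundle[name].copy()
        if len(frame.columns) and len(frame):
            frame = frame.sort_values(list(frame.columns[:1]), kind="stable")
        fname = f"{name}.tsv"
        fpath = out_dir / fname
        frame.to_csv(fpath, sep="\t", index=False, lineterminator="\n")
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        entries.append({"file": fname, "rows": int(len(frame)), "sha256": digest})
    manifest = {
        "files": entries,
        "config": dict(config) if config else {},
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return pd.DataFrame(entries)
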