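"""Tiling-peptide matrix design: spots, PTM variants, regions, descriptors.

A matrix design is an ordered list of :class:`TilingPeptide` spots. Unmodified
spots tile the parent protein with a fixed window (default 14 residues) and
offset (default 4), so neighbouring spots share ``length - offset`` residues;
a short linear motif fully contained in several consecutive windows therefore
leaves a multi-spot signal. Modified spots carry one or more side-chain PTMs
and share coordinates and ``tile_index`` with their unmodified parent spot.

All protein coordinates are 1-based inclusive; ``tile_index`` is the 0-based
ordinal of the unmodified tile in sequence order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: residue each modification type is chemically compatible with
MOD_RESIDUE = {
    "phospho_S": "S",
    "phospho_T": "T",
    "phospho_Y": "Y",
    "acetyl_K": "K",
    "methyl_K": "K",
    "methyl_R": "R",
    "citrulline_R": "R",
}

# pKa sets for the composition-based Henderson-Hasselbalch charge model.
# Keys: termini plus ionizable side chains. Values from the named sources.
PKA_TABLES = {
    "EMBOSS": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "Lehninger": {
        "Nterm": 9.69, "Cterm": 2.34,
        "K": 10.5, "R": 12.4, "H": 6.0,
        "D": 3.86, "E": 4.25, "C": 8.33, "Y": 10.0,
    },
}


@dataclass(frozen=True)
class ProteinSequence:
    """A parent protein: identifier plus residue string (1-based positions)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-standard residues: {sorted(bad)}"
            )
        if len(self.residues) < 1:
            raise ValueError("protein sequence must contain at least one residue")

    @property
    def length(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int) -> str:
        """Residues at 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"coordinates [{start}, {end}] outside [1, {self.length}]")
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class PTMAnnotation:
    """One candidate post-translational modification site on the parent protein."""

    position: int  # 1-based protein coordinate
    residue: str
    mod_type: str

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_RESIDUE:
            raise ValueError(f"unknown mod_type {self.mod_type!r}")
        if MOD_RESIDUE[self.mod_type] != self.residue:
            raise ValueError(
                f"mod_type {self.mod_type} is not compatible with residue "
                f"{self.residue!r} at position {self.position}"
            )

    def validate_against(self, protein: ProteinSequence) -> None:
        actual = protein.residues[self.position - 1]
        if actual != self.residue:
            raise ValueError(
                f"PTM {self.mod_type}@{self.position} expects residue "
                f"{self.residue!r} but protein {protein.id!r} has {actual!r}"
            )


@dataclass(frozen=True)
class TilingPeptide:
    """One matrix spot (unmodified tile or PTM variant of one)."""

    spot_id: str
    start: int
    end: int
    sequence: str
    ptms: tuple[PTMAnnotation, ...] = ()
    parent_spot_id: str = ""
    tile_index: int = -1

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"spot {self.spot_id!r}: sequence length {len(self.sequence)} "
                f"does not match [{self.start}, {self.end}]"
            )
        for ptm in self.ptms:
            if not (self.start <= ptm.position <= self.end):
                raise ValueError(
                    f"spot {self.spot_id!r}: PTM at {ptm.position} lies outside "
                    f"[{self.start}, {self.end}]"
                )

    @property
    def is_modified(self) -> bool:
        return bool(self.ptms)


@dataclass(frozen=True)
class RegionAnnotation:
    """Named protein segment (conserved region, IDR, DNA-binding, zipper...)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"region {self.name!r}: invalid interval")


def tile_sequence(
    protein: ProteinSequence,
    length: int = 14,
    offset: int = 4,
    tail_policy: str = "anchor_c_terminus",
) -> list[TilingPeptide]:
    """Tile a protein into fixed-length overlapping peptides.

    Starts run 1, 1+offset, 1+2*offset, ... as long as the window fits. Under
    ``tail_policy="anchor_c_terminus"`` a final window ending exactly at the
    C-terminus is appended when the last regular window falls short of it, so
    the union of windows always covers the full sequence; ``"drop"`` leaves
    the tail uncovered.
    """
    if tail_policy not in ("anchor_c_terminus", "drop"):
        raise ValueError(f"unknown tail_policy {tail_policy!r}")
    if offset < 1:
        raise ValueError("offset must be >= 1")
    if length > protein.length:
        raise ValueError(
            f"protein {protein.id!r} ({protein.length} aa) is shorter than the "
            f"peptide length {length}"
        )
    starts = list(range(1, protein.length - length + 2, offset))
    if tail_policy == "anchor_c_terminus" and starts[-1] + length - 1 < protein.length:
        starts.append(protein.length - length + 1)
    tiles = []
    for idx, start in enumerate(starts):
        end = start + length - 1
        spot_id = f"t{idx + 1:03d}"
        tiles.append(
            TilingPeptide(
                spot_id=spot_id,
                start=start,
                end=end,
                sequence=protein.subsequence(start, end),
                parent_spot_id=spot_id,
                tile_index=idx,
            )
        )
    return tiles


def expand_ptm_variants(
    tiles: Sequence[TilingPeptide],
    ptms: Sequence[PTMAnnotation],
    protein: ProteinSequence,
    policy: str = "single_ptm",
) -> list[TilingPeptide]:
    """Create modified spot variants for every (covering tile, PTM) pair.

    Under the default ``single_ptm`` policy each variant carries exactly one
    modification; ``combinations`` additionally emits every multi-PTM subset
    of the modifications covered by a tile. Variants inherit coordinates,
    sequence and ``tile_index`` from their parent spot; spot ids follow
    ``<parent>+<mod_type><position>``.
    """
    if policy not in ("single_ptm", "combinations"):
        raise ValueError(f"unknown policy {policy!r}")
    for ptm in ptms:
        ptm.validate_against(protein)
    variants: list[TilingPeptide] = []
    for tile in tiles:
        if tile.is_modified:
            continue
        covered = [p for p in ptms if tile.start <= p.position <= tile.end]
        if policy == "single_ptm":
            groups: Iterable[tuple[PTMAnnotation, ...]] = [(p,) for p in covered]
        else:
            groups = itertools.chain.from_iterable(
                itertools.combinations(covered, r) for r in range(1, len(covered) + 1)
            )
        for group in groups:
            suffix = "+".join(f"{p.mod_type}{p.position}" for p in group)
            variants.append(
                TilingPeptide(
                    spot_id=f"{tile.spot_id}+{suffix}",
                    start=tile.start,
                    end=tile.end,
                    sequence=tile.sequence,
                    ptms=tuple(group),
                    parent_spot_id=tile.spot_id,
                    tile_index=tile.tile_index,
                )
            )
    return variants


def annotate_regions(
    tile: TilingPeptide, regions: Sequence[RegionAnnotation]
) -> list[str]:
    """Names of all regions whose interval intersects the tile's interval."""
    return [r.name for r in regions if r.start <= tile.end and tile.start <= r.end]


def peptide_gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
    if not sequence:
        raise ValueError("empty peptide")
    return sum(_KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


def peptide_net_charge(sequence: str, ph: float, pka_table: str = "EMBOSS") -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Composition-based: free N- and C-termini plus ionizable side chains
    (K, R, H positive; D, E, C, Y negative).
    """
    pka = PKA_TABLES[pka_table]
    positive = ["Nterm"] + [aa for aa in sequence if aa in "KRH"]
    negative = ["Cterm"] + [aa for aa in sequence if aa in "DECY"]
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka[g])) for g in positive)
    charge -= sum(1.0 / (1.0 + 10 ** (pka[g] - ph)) for g in negative)
    return charge


def peptide_isoelectric_point(
    sequence: str, pka_table: str = "EMBOSS", tol: float = 1e-6
) -> float:
    """pH at which the peptide's Henderson-Hasselbalch net charge is zero.

    Found by bisection on [0, 14]; the charge is strictly decreasing in pH so
    the root is unique. Raises if the charge does not change sign on [0, 14]
    or bisection fails to reach ``|charge| < tol``.
    """
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
    if pka_table not in PKA_TABLES:
        raise ValueError(
            f"unknown pKa table {pka_table!r}; available: {sorted(PKA_TABLES)}"
        )
    lo, hi = 0.0, 14.0
    c_lo = peptide_net_charge(sequence, lo, pka_table)
    c_hi = peptide_net_charge(sequence, hi, pka_table)
    if c_lo < 0 or c_hi > 0:
        raise ValueError("net charge does not cross zero within pH [0, 14]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = peptide_net_charge(sequence, mid, pka_table)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    raise ValueError("isoelectric point bisection did not converge")


# ---------------------------------------------------------------------------
# Default design
# ---------------------------------------------------------------------------

# Deterministic synthetic 297-residue parent protein for the bundled default
# design (the real screen's parent sequence and per-spot PTM layout are not
# redistributable). Residue composition is uniform over the 20 standard amino
# acids, generated once and frozen here.
_SYNTHETIC_PROTEIN_297 = (
    "MKRSDTLYEQWAGHVFNPCIKSRTYLDEAGQWHNVFPMCIESKRTADYLGHQWVNFPICM"
    "SRKTYEDLAGWQHVNPFCIMSEKRADTYLQGWHVFNPICMKSRETDYLAWGQHVNFPCIM"
    "SKRATDYELGWQHVFNPICSMKRTDYEALGWQHVNFPCIMSKRDTYEALGQWHVFNPICM"
    "SKRTDEYALGWQHVNFPICMSRKTDYEALGWQHVFNPCIMSKRTDYELAGWQHVNFPICM"
    "SKRTDYEALGWQHVFNPICMSKRTDYEALGWQHVNFPICMSKRTDYEALGWQHVFNP"
)


def default_design(
    n_spots: int = 203, pka_table: str = "EMBOSS"
) -> tuple[ProteinSequence, list[TilingPeptide]]:
    """Bundled default matrix design: a synthetic 297-aa parent protein tiled
    into 72 unmodified 14-mers (offset 4, C-anchored tail) plus PTM-variant
    spots up to ``n_spots`` total (default 203, the screen's spot count).

    PTM variants are taken in spot order from all chemically valid single-PTM
    annotations of the synthetic sequence, so the design is deterministic.
    """
    protein = ProteinSequence("SYN297", _SYNTHETIC_PROTEIN_297)
    tiles = tile_sequence(protein)
    if n_spots < len(tiles):
        raise ValueError(f"n_spots must be >= {len(tiles)} (number of tiles)")
    mod_cycle = {
        "S": ["phospho_S"],
        "T": ["phospho_T"],
        "Y": ["phospho_Y"],
        "K": ["acetyl_K", "methyl_K"],
        "R": ["methyl_R", "citrulline_R"],
    }
    counters: dict[str, int] = {}
    ptms = []
    for pos, aa in enumerate(protein.residues, start=1):
        if aa in mod_cycle:
            k = counters.get(aa, 0)
            mods = mod_cycle[aa]
            ptms.append(PTMAnnotation(pos, aa, mods[k % len(mods)]))
            counters[aa] = k + 1
    variants = expand_ptm_variants(tiles, ptms, protein)
    n_variants = n_spots - len(tiles)
    if n_variants > len(variants):
        raise ValueError(
            f"requested {n_variants} PTM-variant spots but only "
            f"{len(variants)} are available"
        )
    design = tiles + variants[:n_variants]
    design.sort(key=lambda t: (t.tile_index, t.spot_id))
    return protein, design


def design_to_frame(design: Sequence[TilingPeptide]):
    """Design as a pandas DataFrame in the on-disk TSV column layout."""
    import pandas as pd

    rows = [
        {
            "spot_id": t.spot_id,
            "sequence": t.sequence,
            "start": t.start,
            "end": t.end,
            "ptms": ";".join(f"{p.mod_type}:{p.position}" for p in t.ptms),
            "parent_spot_id": t.parent_spot_id,
            "tile_index": t.tile_index,
        }
        for t in design
    ]
    return pd.DataFrame(rows)


def design_from_frame(frame) -> list[TilingPeptide]:
    """Inverse of :func:`design_to_frame`."""
    design = []
    for row in frame.itertuples(index=False):
        ptms = []
        if isinstance(row.ptms, str) and row.ptms:
            for token in row.ptms.split(";"):
                mod_type, pos = token.rsplit(":", 1)
                ptms.append(PTMAnnotation(int(pos), MOD_RESIDUE[mod_type], mod_type))
        design.append(
            TilingPeptide(
                spot_id=str(row.spot_id),
                start=int(row.start),
                end=int(row.end),
                sequence=str(row.sequence),
                ptms=tuple(ptms),
                parent_spot_id=str(row.parent_spot_id),
                tile_index=int(row.tile_index),
            )
        )
    return design
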