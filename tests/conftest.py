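import numpy as np
import pytest

from prisma_screen.matrix_design import (
    ProteinSequence,
    PTMAnnotation,
    TilingPeptide,
    default_design,
    expand_ptm_variants,
    tile_sequence,
)


@pytest.fixture(scope="session")
def design_203():
    """Bundled default design: 72 tiles + 131 PTM-variant spots."""
    protein, design = default_design()
    return protein, design


@pytest.fixture(scope="session")
def toy_design():
    """Small design: 40-residue protein, 14-mers at offset 4, two PTM sites.

    Tile starts 1, 5, ..., 25 plus the C-anchored tail [27, 40] (8 tiles).
    The methyl_R site at position 20 is covered by the tiles starting at
    9, 13 and 17; the acetyl_K site at position 21 additionally by the tile
    starting at 21 — so the t003/t004/t005 groups carry two variants each
    and the t006 group one (15 spots in total).
    """
    residues = "MKSADTLYEQWAGHVFNPCRKSDTYLAEGQWHNVFPMCIE"
    protein = ProteinSequence("TOY40", residues)
    tiles = tile_sequence(protein)
    ptms = [PTMAnnotation(20, "R", "methyl_R"), PTMAnnotation(21, "K", "acetyl_K")]
    design = tiles + expand_ptm_variants(tiles, ptms, protein)
    design.sort(key=lambda t: (t.tile_index, t.spot_id))
    return protein, design


def make_profile_values(design, spot_values):
    """Dense value vector over a design from a {spot_id: value} mapping."""
    return np.array([float(spot_values.get(t.spot_id, 0.0)) for t in design])
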