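"""Small worked-example datasets.

The eQTL-overlap example reconstructs, at the sentinel-gene pair level, the
published comparison between a physical promoter-capture variant-to-gene map
and a 41-association eQTL catalog, of which 14 gene associations were
recovered by the physical map (ANKS1A, C6orf106, RMI2, SOCS1, PXK,
UHRF1BP1, LYST, NADSYN1, DHCR7, C15orf39, MPI, CSK, ULK3, FAM219B). The
gene symbols of the shared pairs are the published ones; the remaining eQTL
pairs and the additional map pairs are synthetic placeholders, since only
the overlapping genes are printed.
"""

from __future__ import annotations

from .enrichment import SentinelGenePair, make_pairs

#: Gene symbols of the 14 eQTL associations recovered by the physical map.
RECOVERED_EQTL_GENES = (
    "ANKS1A",
    "C6orf106",
    "RMI2",
    "SOCS1",
    "PXK",
    "UHRF1BP1",
    "LYST",
    "NADSYN1",
    "DHCR7",
    "C15orf39",
    "MPI",
    "CSK",
    "ULK3",
    "FAM219B",
)

#: Size of the eQTL catalog in the published comparison.
EQTL_CATALOG_SIZE = 41


def eqtl_overlap_example() -> tuple[set[SentinelGenePair], set[SentinelGenePair]]:
    """(v2g_pairs, eqtl_pairs) reproducing the 14-of-41 overlap.

    Shared pairs use the published gene symbols; filler pairs (synthetic)
    use distinct sentinels and symbols so they cannot collide.
    """
    shared = [(f"rsSHARED{i:02d}", g) for i, g in enumerate(RECOVERED_EQTL_GENES)]
    n_filler = EQTL_CATALOG_SIZE - len(shared)
    eqtl_only = [(f"rsEQTL{i:02d}", f"SYNEQG{i:02d}") for i in range(n_filler)]
    v2g_only = [(f"rsV2G{i:03d}", f"SYNV2G{i:03d}") for i in range(60)]
    return make_pairs(shared + v2g_only), make_pairs(shared + eqtl_only)
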