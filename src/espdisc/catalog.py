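"""Demonstration catalog of LC-MS/MS-validated O. grahami mature peptides.

Sixteen frog-skin-family mature peptides validated at the protein level in
a single O. grahami skin specimen, with their master-protein accessions and
the number of truncated forms observed alongside each.  The catalog serves
as the species-tier ("OG") reference for provenance classification and as a
small worked dataset: every entry carries a C-terminal Rana box, and each
mature peptide was more abundant and longer than all of its truncations.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    mature: str
    master_accessions: tuple[str, ...]
    n_truncated: int


DEMO_CATALOG: tuple[CatalogEntry, ...] = (
    CatalogEntry("brevinin-1E-OG3", "FLPLLAGLAANFLPKLFCKITKKC", ("TRINITY_DN0_c1_g1_i24.p1",), 7),
    CatalogEntry("brevinin-2E-OG1", "GLLDTFKNMALNAAKSAGVSVLNALSCKLSKTC", ("TRINITY_DN440_c40_g1_i1.p1",), 13),
    CatalogEntry(
        "brevinin-2GRa",
        "GLLDTFKNLALNAAKSAGVSVLNSLSCKLSKTC",
        ("TRINITY_DN0_c1_g1_i14.p1", "TRINITY_DN0_c1_g1_i4.p1"),
        28,
    ),
    CatalogEntry("brevinin-2GRb", "GVLGTVKNLLIGAGKSAAQSVLKTLSCKLSNDC", ("TRINITY_DN0_c1_g1_i11.p1",), 17),
    CatalogEntry(
        "esculentin-1-OG5",
        "GLFSKFAGKGIKDLIFKGVKHIGKEVGMDVIRTGIDVAGCKIKGEC",
        ("TRINITY_DN0_c1_g1_i16.p1",),
        9,
    ),
    CatalogEntry(
        "esculentin-2-OG10",
        "GLFTLIKGAAKLIGKTVAKEAGKTGLELMACKITNQC",
        ("TRINITY_DN0_c1_g1_i22.p1",),
        26,
    ),
    CatalogEntry(
        "esculentin-2-OG8",
        "GIFSILKIATKLIGKTLAKAAGKAGAELAACKAANQC",
        ("TRINITY_DN96_c0_g2_i2.p1",),
        1,
    ),
    CatalogEntry(
        "esculentin-2-RA1",
        "GIFAILKIATKLIGKTLAKAAGKAGTGLLACKAAKEC",
        ("TRINITY_DN96_c0_g1_i2.p1",),
        1,
    ),
    CatalogEntry("nigrocin-2GRa", "GLLSGILGAGKHIVCGLSGLC", ("TRINITY_DN77_c0_g1_i1.p1_ORF1",), 3),
    CatalogEntry("nigrocin-2GRb", "GLFGKILGVGKKVLCGLSGMC", ("TRINITY_DN49_c0_g1_i1.p1_ORF1",), 6),
    CatalogEntry("nigrocin-2GRc", "GLLSGILGAGKNIVCGLSGLC", ("TRINITY_DN0_c1_g1_i17.p1",), 1),
    CatalogEntry("odorranain-C13", "GVLGTVKNLLIGASKSAAQSVLKTLSCKLSNDC", ("TRINITY_DN2658_c0_g2_i1.p1",), 10),
    CatalogEntry("odorranain-F2", "GFMDTAKNVAKNVAVTLLDNLKCKITKAC", ("TRINITY_DN10285_c0_g1_i1.p1",), 3),
    CatalogEntry("odorranain-P1b", "VIPFVASVAAEMMQHVYCAASKKC", ("TRINITY_DN5345_c0_g1_i2.p1",), 0),
    CatalogEntry("OGT", "IAVNIPFKVHFRCKAAFC", ("TRINITY_DN0_c1_g1_i20.p1",), 0),
    CatalogEntry("ranatuerin-2P-OG1", "GLMNTVLNVLTNVAGTVKDKIKCKFTGGC", ("TRINITY_DN6_c2_g1_i1.p1",), 1),
)


def demo_mature_sequences() -> list[str]:
    return [entry.mature for entry in DEMO_CATALOG]


def demo_fasta_items() -> list[tuple[str, str]]:
    return [(entry.name, entry.mature) for entry in DEMO_CATALOG]


def total_truncated() -> int:
    """Sum of observed truncated forms across the catalog."""
    return sum(entry.n_truncated for entry in DEMO_CATALOG)
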