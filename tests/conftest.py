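"""Shared fixtures: the published ALB/DBP/SERPING1/ANXA1/PRKDC peptide
panel and synthetic mini-proteomes built from it."""

from __future__ import annotations

import pytest

from surroquant import PanelDefinition, ProteinRecord, write_fasta

# Published MRM panel: human analyte peptides and their bovine surrogate
# IS peptides, with the printed (M+2H)2+ precursor m/z (1 dp).
TABLE1_PRECURSORS = {
    "LVNEVTEFAK": 575.3,
    "LVNELTEFAK": 582.3,
    "QTALVELVK": 500.8,
    "QTALVELLK": 507.8,
    "TSALSAK": 339.2,
    "TSALSDK": 361.2,
    "VLEPTLK": 400.2,
    "ILESTLK": 402.2,
    "FQPTLLTLPR": 593.4,
    "FHPTHLTMPR": 618.8,
    "GVDEATIIDILTK": 694.4,
    "GVDEATIIEILTK": 701.4,
    "DQNILLGTTYR": 647.3,
    "DHHVLLGTTYR": 656.3,
}

# Printed singly charged product ions that reproduce from standard
# residue masses (the published "448.3 [y5]" of ILESTLK is actually the
# y4 ion and the "299.2 [y5]" of DHHVLLGTTYR is the 2+ y5; both are
# excluded here and covered by dedicated tests).
TABLE1_PRODUCTS = [
    ("LVNEVTEFAK", "y", 5, 595.3),
    ("LVNEVTEFAK", "y", 6, 694.4),
    ("LVNELTEFAK", "y", 6, 708.4),
    ("LVNELTEFAK", "y", 7, 837.4),
    ("QTALVELVK", "y", 6, 700.5),
    ("QTALVELVK", "y", 7, 771.5),
    ("QTALVELLK", "y", 6, 714.5),
    ("QTALVELLK", "y", 7, 785.5),
    ("TSALSAK", "y", 5, 489.3),
    ("TSALSAK", "y", 6, 576.3),
    ("TSALSDK", "y", 5, 533.3),
    ("TSALSDK", "y", 6, 620.3),
    ("VLEPTLK", "y", 5, 587.3),
    ("VLEPTLK", "y", 6, 700.4),
    ("ILESTLK", "y", 6, 690.4),
    ("FQPTLLTLPR", "y", 4, 486.3),
    ("FQPTLLTLPR", "y", 5, 599.4),
    ("FQPTLLTLPR", "y", 6, 712.5),
    ("FQPTLLTLPR", "y", 8, 910.6),
    ("FHPTHLTMPR", "y", 4, 504.3),
    ("FHPTHLTMPR", "y", 5, 617.3),
    ("FHPTHLTMPR", "y", 8, 952.5),
    ("FHPTHLTMPR", "y", 9, 1089.6),
    ("GVDEATIIDILTK", "y", 6, 702.4),
    ("GVDEATIIDILTK", "y", 7, 815.5),
    ("GVDEATIIDILTK", "y", 8, 916.6),
    ("GVDEATIIDILTK", "y", 9, 987.6),
    ("GVDEATIIEILTK", "y", 6, 716.5),
    ("GVDEATIIEILTK", "y", 8, 930.6),
    ("GVDEATIIEILTK", "b", 9, 928.5),
    ("GVDEATIIEILTK", "b", 10, 1041.5),
    ("DQNILLGTTYR", "y", 5, 597.3),
    ("DQNILLGTTYR", "y", 6, 710.4),
    ("DQNILLGTTYR", "y", 7, 823.5),
    ("DQNILLGTTYR", "b", 3, 358.1),
    ("DHHVLLGTTYR", "y", 7, 823.5),
    ("DHHVLLGTTYR", "y", 8, 922.5),
    ("DHHVLLGTTYR", "b", 2, 253.1),
]

# Published GRAVY (Kyte-Doolittle) indices that reproduce at 2 dp.
TABLE1_GRAVY = {
    "LVNEVTEFAK": 0.17,
    "LVNELTEFAK": 0.13,
    "QTALVELVK": 0.69,
    "QTALVELLK": 0.64,
    "TSALSAK": 0.17,
}

# Human analyte peptide -> bovine surrogate peptide.
TABLE1_PAIRINGS = {
    "LVNEVTEFAK": "LVNELTEFAK",
    "QTALVELVK": "QTALVELLK",
    "TSALSAK": "TSALSDK",
    "VLEPTLK": "ILESTLK",
    "FQPTLLTLPR": "FHPTHLTMPR",
    "GVDEATIIDILTK": "GVDEATIIEILTK",
    "DQNILLGTTYR": "DHHVLLGTTYR",
}

# Mini-proteins embedding the panel peptides as clean tryptic products:
# the "MK" prefix opens the first peptide and every peptide ends in K/R.
HUMAN_MINIPROTEOME = {
    "ALB_HUMAN": "MK" + "LVNEVTEFAK" + "QTALVELVK",
    "DBP_HUMAN": "MK" + "TSALSAK" + "VLEPTLK",
    "SERPING1_HUMAN": "MK" + "FQPTLLTLPR",
    "ANXA1_HUMAN": "MK" + "GVDEATIIDILTK",
    "PRKDC_HUMAN": "MK" + "DQNILLGTTYR",
}
BOVINE_MINIPROTEOME = {
    "ALB_BOVIN": "MK" + "LVNELTEFAK" + "QTALVELLK",
    "DBP_BOVIN": "MK" + "TSALSDK" + "ILESTLK",
    "SERPING1_BOVIN": "MK" + "FHPTHLTMPR",
    "ANXA1_BOVIN": "MK" + "GVDEATIIEILTK",
    "PRKDC_BOVIN": "MK" + "DHHVLLGTTYR",
}


@pytest.fixture
def panel_records() -> list[tuple[ProteinRecord, ProteinRecord]]:
    return [
        (
            ProteinRecord(hid, "human", hseq),
            ProteinRecord(bid, "bovine", bseq),
        )
        for (hid, hseq), (bid, bseq) in zip(
            HUMAN_MINIPROTEOME.items(), BOVINE_MINIPROTEOME.items()
        )
    ]


@pytest.fixture
def table1_panel(panel_records) -> PanelDefinition:
    return PanelDefinition(entries=panel_records)


@pytest.fixture
def panel_fastas(tmp_path, panel_records):
    """FASTA files for the two mini-proteomes; returns (human, bovine) paths."""
    human = tmp_path / "human.fasta"
    bovine = tmp_path / "bovine.fasta"
    write_fasta([t for t, _ in panel_records], human)
    write_fasta([s for _, s in panel_records], bovine)
    return human, bovine
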