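"""Mouse genome constants and chromosome-label handling.

Chromosome lengths follow GRCm39 (Mus musculus reference 39); the three
chromosomes central to the analysis are 195.15 Mb (Chr 1), 156.86 Mb
(Chr 4) and 124.36 Mb (Chr 9).  Labels are stored unprefixed ("1", "X");
a "chr" prefix is accepted and stripped on input.
"""

from __future__ import annotations

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))
SEX_CHROMOSOMES: tuple[str, ...] = ("X", "Y")
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMOSOMES

#: GRCm39 assembled chromosome lengths in bp.
CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 195_154_279,
    "2": 181_755_017,
    "3": 159_745_316,
    "4": 156_860_686,
    "5": 151_758_149,
    "6": 149_588_044,
    "7": 144_995_196,
    "8": 130_127_694,
    "9": 124_359_700,
    "10": 130_530_862,
    "11": 121_973_369,
    "12": 120_092_757,
    "13": 120_883_175,
    "14": 125_139_656,
    "15": 104_073_951,
    "16": 98_008_968,
    "17": 95_294_699,
    "18": 90_720_763,
    "19": 61_420_004,
    "X": 169_476_592,
    "Y": 91_455_967,
}

#: SV40-immortalized male fibroblasts are tetraploid: four copies of each
#: autosome, two copies of each sex chromosome.
TETRAPLOID_MALE_KARYOTYPE: dict[str, int] = {
    **{c: 4 for c in AUTOSOMES},
    "X": 2,
    "Y": 2,
}


def normalize_chrom(label: object) -> str:
    """Normalize a chromosome label to the unprefixed convention.

    "chr1" -> "1", "ChrX" -> "X", 1 -> "1".  Unknown labels are returned
    normalized but unvalidated; callers decide whether to warn.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in ("x", "y", "mt") else s


def is_known_chrom(label: str) -> bool:
    return label in CHROM_LENGTHS_BP or label == "MT"
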