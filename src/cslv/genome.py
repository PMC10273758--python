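"""Reference chromosome lengths (GRCh38, UCSC chrom.sizes values)."""

# Autosome lengths in bp. Chromosome 1 is ~249 Mb; simulated cohorts use
# these so that genomic coordinates look like real SNP-array data.
GRCH38_AUTOSOMES: dict[str, int] = {
    "1": 248_956_422,
    "2": 242_193_529,
    "3": 198_295_559,
    "4": 190_214_555,
    "5": 181_538_259,
    "6": 170_805_979,
    "7": 159_345_973,
    "8": 145_138_636,
    "9": 138_394_717,
    "10": 133_797_422,
    "11": 135_086_622,
    "12": 133_275_309,
    "13": 114_364_328,
    "14": 107_043_718,
    "15": 101_991_189,
    "16": 90_338_345,
    "17": 83_257_441,
    "18": 80_373_285,
    "19": 58_617_616,
    "20": 64_444_167,
    "21": 46_709_983,
    "22": 50_818_468,
}

GRCH38_X: int = 156_040_895


def grch38_sizes(include_x: bool = False) -> dict[str, int]:
    """Chromosome name -> length mapping for the 22 autosomes (+ X)."""
    sizes = dict(GRCH38_AUTOSOMES)
    if include_x:
        sizes["X"] = GRCH38_X
    return sizes
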