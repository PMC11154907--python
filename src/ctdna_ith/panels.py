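"""Packaged gene panels and nominal gene intervals.

Two panels ship with the package: the 19 genes most frequently mutated in
HNSCC according to TCGA exome data (used to call tumour variants) and the
9-gene targeted plasma panel (TP53, NOTCH1, PIK3CA, KMT2D, CDKN2A, CASP8,
NSD1, FAT1, FBXW7) used for cell-free DNA sequencing.

The interval file gives each panel gene a nominal hg38-like genomic span.
These spans are synthetic placement windows for the simulator — no reference
genome or real exon structure is involved; the analysis itself never uses
coordinates beyond variant identity.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("ctdna_ith") / "data"


def _read_gene_list(name: str) -> list[str]:
    text = (_DATA / name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def tcga_hnscc_genes() -> list[str]:
    """The 19-gene TCGA HNSCC panel used for tumour variant calling."""
    return _read_gene_list("tcga_hnscc_19_genes.txt")


def plasma_panel_genes() -> list[str]:
    """The 9-gene targeted plasma (cell-free DNA) panel."""
    return _read_gene_list("plasma_panel_9_genes.txt")


def gene_intervals() -> pd.DataFrame:
    """Nominal per-gene intervals (columns gene, chrom, start, end)."""
    with resources.as_file(_DATA / "gene_intervals.tsv") as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df
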