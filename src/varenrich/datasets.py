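"""Published reference values for regression checks.

Per-pathway contingency counts from a group-level variant enrichment study
of asbestos-exposed shipyard workers (three necropsy groups: unaffected
controls CTRL, lung cancer LC, malignant pleural mesothelioma MPM), tested
against the gnomAD non-Finnish European background. Each row carries the
group-common variant count in the pathway (a), the group-common total (n1),
the background count (c) and background total (n2 = 180,208), together with
the enrichment statistics as printed in the published report (OR, 95% CI,
FDR-adjusted p). The printed "OR" column is the enrichment ratio
(a/n1)/(c/n2) as estimated by a conditional-exact analysis of the
(count, total) table, not the cross-product odds ratio.

These rows are *inputs* for validating the statistics of
:mod:`varenrich.enrichment`; they are not produced by this package.
"""

from __future__ import annotations

from typing import NamedTuple

BACKGROUND_TOTAL = 180_208


class PublishedRow(NamedTuple):
    group: str
    pathway_id: str
    pathway_name: str
    a: int
    n1: int
    c: int
    n2: int
    or_printed: float
    ci_low_printed: float
    ci_high_printed: float
    adj_p_printed: float


_N = BACKGROUND_TOTAL

PUBLISHED_ENRICHMENT = (
    PublishedRow("CTRL", "R-HSA-164940", "Nef-mediated downregulation of MHC class I complex cell surface expression", 12, 5610, 69, _N, 5.59, 2.75, 10.40, 1.43e-2),
    PublishedRow("CTRL", "R-HSA-2172127", "DAP12 interactions", 26, 5610, 311, _N, 2.69, 1.73, 4.02, 4.02e-2),
    PublishedRow("CTRL", "R-HSA-5083632", "Defective C1GALT1C1 causes Tn polyagglutination syndrome (TNPS)", 148, 5610, 1809, _N, 2.63, 2.20, 3.12, 1.42e-19),
    PublishedRow("CTRL", "R-HSA-977068", "Termination of O-glycan biosynthesis", 151, 5610, 1847, _N, 2.63, 2.21, 3.11, 5.57e-20),
    PublishedRow("CTRL", "R-HSA-5083625", "Defective GALNT3 causes familial hyperphosphatemic tumoral calcinosis (HFTC)", 148, 5610, 1811, _N, 2.63, 2.20, 3.11, 1.55e-19),
    PublishedRow("CTRL", "R-HSA-5083636", "Defective GALNT12 causes colorectal cancer 1 (CRCS1)", 148, 5610, 1812, _N, 2.62, 2.20, 3.11, 1.61e-19),
    PublishedRow("CTRL", "R-HSA-5621480", "Dectin-2 family", 151, 5610, 1892, _N, 2.56, 2.15, 3.03, 4.49e-19),
    PublishedRow("CTRL", "R-HSA-198933", "Immunoregulatory interactions between a lymphoid and a non-lymphoid cell", 99, 5610, 1750, _N, 1.82, 1.47, 2.23, 3.00e-4),
    PublishedRow("LC", "R-HSA-1839128", "FGFR4 mutant receptor activation", 6, 4102, 16, _N, 16.48, 5.28, 44.31, 1.63e-2),
    PublishedRow("LC", "R-HSA-3656237", "Defective EXT2 causes exostoses 2", 20, 4102, 211, _N, 4.16, 2.49, 6.60, 8.21e-4),
    PublishedRow("LC", "R-HSA-3656253", "Defective EXT1 causes exostoses 1, TRPS2 and CHDS", 20, 4102, 211, _N, 4.16, 2.49, 6.60, 8.21e-4),
    PublishedRow("LC", "R-HSA-2024096", "HS-GAG degradation", 25, 4102, 312, _N, 3.52, 2.24, 5.30, 6.02e-4),
    PublishedRow("LC", "R-HSA-3560801", "Defective B3GAT3 causes JDSSDHD", 21, 4102, 270, _N, 3.42, 2.08, 5.34, 8.07e-3),
    PublishedRow("LC", "R-HSA-4420332", "Defective B3GALT6 causes EDSP2 and SEMDJL1", 20, 4102, 266, _N, 3.30, 1.98, 5.21, 2.17e-2),
    PublishedRow("LC", "R-HSA-3560783", "Defective B4GALT7 causes EDS, progeroid type", 20, 4102, 269, _N, 3.27, 1.96, 5.15, 2.52e-2),
    PublishedRow("LC", "R-HSA-1971475", "A tetrasaccharide linker sequence is required for GAG synthesis", 21, 4102, 304, _N, 3.03, 1.85, 4.73, 4.33e-2),
    PublishedRow("LC", "R-HSA-975634", "Retinoid metabolism and transport", 32, 4102, 571, _N, 2.46, 1.67, 3.52, 2.48e-2),
    PublishedRow("LC", "R-HSA-977068", "Termination of O-glycan biosynthesis", 93, 4102, 1847, _N, 2.21, 1.77, 2.73, 6.91e-8),
    PublishedRow("LC", "R-HSA-5083632", "Defective C1GALT1C1 causes Tn polyagglutination syndrome (TNPS)", 91, 4102, 1809, _N, 2.21, 1.77, 2.74, 1.22e-7),
    PublishedRow("LC", "R-HSA-5083625", "Defective GALNT3 causes familial hyperphosphatemic tumoral calcinosis (HFTC)", 91, 4102, 1811, _N, 2.21, 1.76, 2.73, 1.26e-7),
    PublishedRow("LC", "R-HSA-5083636", "Defective GALNT12 causes colorectal cancer 1 (CRCS1)", 91, 4102, 1812, _N, 2.21, 1.76, 2.73, 1.29e-7),
    PublishedRow("LC", "R-HSA-5621480", "Dectin-2 family", 92, 4102, 1892, _N, 2.14, 1.71, 2.64, 5.42e-7),
    PublishedRow("MPM", "R-HSA-5619063", "Defective SLC29A3 causes histiocytosis-lymphadenopathy plus syndrome (HLAS)", 6, 7745, 9, _N, 15.51, 4.54, 48.84, 4.32e-2),
    PublishedRow("MPM", "R-HSA-1839128", "FGFR4 mutant receptor activation", 9, 7745, 16, _N, 13.09, 5.10, 31.46, 9.35e-4),
    PublishedRow("MPM", "R-HSA-1307965", "betaKlotho-mediated ligand binding", 9, 7745, 21, _N, 9.97, 4.02, 22.72, 5.43e-3),
    PublishedRow("MPM", "R-HSA-2172127", "DAP12 interactions", 57, 7745, 311, _N, 4.26, 3.15, 5.68, 3.79e-14),
    PublishedRow("MPM", "R-HSA-2995410", "Nuclear envelope (NE) reassembly", 17, 7745, 93, _N, 4.25, 2.38, 7.19, 6.90e-3),
    PublishedRow("MPM", "R-HSA-2168880", "Scavenging of heme from plasma", 17, 7745, 108, _N, 3.66, 2.06, 6.14, 3.97e-2),
    PublishedRow("MPM", "R-HSA-3656237", "Defective EXT2 causes exostoses 2", 26, 7745, 211, _N, 2.87, 1.83, 4.32, 1.66e-2),
    PublishedRow("MPM", "R-HSA-3656253", "Defective EXT1 causes exostoses 1, TRPS2 and CHDS", 26, 7745, 211, _N, 2.87, 1.83, 4.32, 1.66e-2),
    PublishedRow("MPM", "R-HSA-8941326", "RUNX2 regulates bone development", 28, 7745, 234, _N, 2.78, 1.81, 4.13, 1.25e-2),
    PublishedRow("MPM", "R-HSA-5663205", "Infectious disease", 256, 7745, 2720, _N, 2.19, 1.92, 2.50, 2.76e-23),
    PublishedRow("MPM", "R-HSA-977068", "Termination of O-glycan biosynthesis", 170, 7745, 1847, _N, 2.14, 1.82, 2.51, 3.42e-14),
    PublishedRow("MPM", "R-HSA-5083632", "Defective C1GALT1C1 causes Tn polyagglutination syndrome (TNPS)", 166, 7745, 1809, _N, 2.14, 1.81, 2.51, 1.12e-13),
    PublishedRow("MPM", "R-HSA-5083625", "Defective GALNT3 causes familial hyperphosphatemic tumoral calcinosis (HFTC)", 166, 7745, 1811, _N, 2.13, 1.81, 2.51, 1.17e-13),
    PublishedRow("MPM", "R-HSA-5083636", "Defective GALNT12 causes colorectal cancer 1 (CRCS1)", 166, 7745, 1812, _N, 2.13, 1.80, 2.50, 1.20e-13),
    PublishedRow("MPM", "R-HSA-975634", "Retinoid metabolism and transport", 51, 7745, 571, _N, 2.08, 1.53, 2.77, 1.56e-2),
    PublishedRow("MPM", "R-HSA-5621480", "Dectin-2 family", 168, 7745, 1892, _N, 2.07, 1.75, 2.42, 9.39e-13),
    PublishedRow("MPM", "R-HSA-3000157", "Laminin interactions", 79, 7745, 988, _N, 1.86, 1.46, 2.34, 2.36e-3),
    PublishedRow("MPM", "R-HSA-909733", "Interferon alpha/beta signaling", 79, 7745, 1010, _N, 1.82, 1.43, 2.29, 6.34e-3),
    PublishedRow("MPM", "R-HSA-198933", "Immunoregulatory interactions between a lymphoid and a non-lymphoid cell", 131, 7745, 1750, _N, 1.74, 1.45, 2.08, 3.45e-5),
    PublishedRow("MPM", "R-HSA-3000171", "Non-integrin membrane–ECM interactions", 108, 7745, 1556, _N, 1.61, 1.31, 1.97, 1.86e-2),
    PublishedRow("MPM", "R-HSA-6805567", "Keratinization", 108, 7745, 1563, _N, 1.61, 1.31, 1.96, 1.97e-2),
    PublishedRow("MPM", "R-HSA-1474228", "Degradation of the extracellular matrix", 185, 7745, 2814, _N, 1.53, 1.31, 1.78, 4.04e-4),
)


def published_enriched_ids() -> dict[str, frozenset[str]]:
    """Per-group enriched pathway-id sets from the published report."""
    out: dict[str, set[str]] = {}
    for row in PUBLISHED_ENRICHMENT:
        out.setdefault(row.group, set()).add(row.pathway_id)
    return {g: frozenset(s) for g, s in out.items()}
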