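"""Gene panels used by the concordance and hypermutation screens.

The defaults are the colorectal-cancer driver panel, the VEGF-receptor
pathway panel, and the DNA mismatch-repair and DNA-polymerase panels screened
in hypermutated samples.  Every panel can be replaced by a plain text file
(one gene symbol per line, ``#`` comments allowed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class GenePanel:
    """A named, non-empty set of gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    @classmethod
    def from_file(cls, name: str, path: str | Path) -> "GenePanel":
        genes = set()
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
        return cls(name=name, genes=frozenset(genes))


#: Key colorectal-cancer driver genes used for pair concordance calls.
DRIVER_PANEL = GenePanel(
    "crc_drivers", frozenset({"APC", "KRAS", "TP53", "SMAD4", "BRAF", "FAT4"})
)

#: VEGF-receptor pathway genes (angiogenesis signalling).
VEGF_PANEL = GenePanel("vegf_pathway", frozenset({"KDR", "FLT1", "FLT4"}))

#: DNA mismatch-repair pathway genes screened in hypermutated samples.
MISMATCH_REPAIR_PANEL = GenePanel(
    "mismatch_repair",
    frozenset(
        {
            "MLH1",
            "MLH3",
            "MSH2",
            "MSH6",
            "PMS2",
            "PMS6",
            "ERCC2",
            "ERCC5",
            "ERCC6",
            "MUTYH",
            "RAD9A",
            "EXO1",
            "SLX4",
            "ATR",
            "BLM",
        }
    ),
)

#: DNA polymerase genes screened in hypermutated samples.
POLYMERASE_PANEL = GenePanel(
    "dna_polymerases",
    frozenset({"POLN", "POLL", "POLQ", "POLH", "POLE", "POLD1", "POLG"}),
)
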