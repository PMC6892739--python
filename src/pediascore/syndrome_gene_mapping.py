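"""Map syndrome-level phenotype scores onto genes via OMIM-dialect files.

Gestalt and semantic-similarity scores are produced per syndrome, but
genes are what an exome analysis ranks; the morbidmap/mim2gene mapping
composes the two, and a gene linked to several scored syndromes takes
the highest score (genetic heterogeneity: any of its syndromes may be
the right one).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

logger = logging.getLogger(__name__)

_MIM_RE = re.compile(r"\b(\d{6})\b")


class MappingFormatError(ValueError):
    pass


@dataclass
class GenePhenotypeMap:
    """Bidirectional syndrome <-> gene mapping (the two dicts are exact inverses)."""

    syndrome_to_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_to_syndromes: dict[str, set[str]] = field(default_factory=dict)

    def add(self, syndrome_id: str, gene: str) -> None:
        gene = gene.strip()
        syndrome_id = syndrome_id.strip()
        if not gene or not syndrome_id:
            return
        self.syndrome_to_genes.setdefault(syndrome_id, set()).add(gene)
        self.gene_to_syndromes.setdefault(gene, set()).add(syndrome_id)

    def edges(self) -> set[tuple[str, str]]:
        return {
            (s, g) for s, genes in self.syndrome_to_genes.items() for g in genes
        }


@dataclass
class SyndromeScoreVector:
    """syndrome_id -> nonnegative similarity score."""

    scores: dict[str, float]


def _syndrome_id_from_label(label: str) -> str:
    """Canonical syndrome id from a morbidmap phenotype label.

    Labels carrying a 6-digit phenotype MIM (``"Some syndrome, 600001
    (3)"`` or ``"OMIM:600001"``) normalize to ``OMIM:600001``; labels
    without one are kept verbatim (trimmed)."""
    m = _MIM_RE.search(label)
    return f"OMIM:{m.group(1)}" if m else label.strip()


def parse_gene_map(
    morbidmap_path: str | Path, mim2gene_path: str | Path | None = None
) -> GenePhenotypeMap:
    """Compose syndrome<->gene links from morbidmap and mim2gene dialects.

    morbidmap rows: ``phenotype-label-with-MIM<TAB>gene symbols
    (comma-separated)<TAB>gene MIM<TAB>cytoband``; mim2gene rows:
    ``MIM<TAB>entry type<TAB>gene id<TAB>symbol`` and are used to
    resolve the gene-MIM column to a symbol.  Comment lines (``#``) are
    skipped; short rows raise with their line number.
    """
    mim_to_symbol: dict[str, str] = {}
    if mim2gene_path is not None:
        with open(mim2gene_path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise MappingFormatError(
                        f"{mim2gene_path}:{ln}: expected 4 tab-separated fields"
                    )
                mim, _entry_type, _gene_id, symbol = parts[:4]
                if symbol.strip():
                    mim_to_symbol[mim.strip()] = symbol.strip()

    gmap = GenePhenotypeMap()
    with open(morbidmap_path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MappingFormatError(
                    f"{morbidmap_path}:{ln}: expected at least 3 tab-separated fields"
                )
            label, symbols, gene_mim = parts[0], parts[1], parts[2]
            syndrome_id = _syndrome_id_from_label(label)
            for sym in symbols.split(","):
                gmap.add(syndrome_id, sym)
            resolved = mim_to_symbol.get(gene_mim.strip())
            if resolved:
                gmap.add(syndrome_id, resolved)
    return gmap


def write_gene_map(gmap: GenePhenotypeMap, morbidmap_path: str | Path,
                   mim2gene_path: str | Path | None = None) -> None:
    """Emit the morbidmap dialect (and an empty-but-valid mim2gene) for a map."""
    with open(morbidmap_path, "w", encoding="utf-8", newline="\n") as fh:
        for syndrome in sorted(gmap.syndrome_to_genes):
            symbols = ",".join(sorted(gmap.syndrome_to_genes[syndrome]))
            fh.write(f"{syndrome}\t{symbols}\t\t\n")
    if mim2gene_path is not None:
        Path(mim2gene_path).write_text(
            "# MIM\tentry type\tgene id\tsymbol\n", encoding="utf-8"
        )


def map_scores_to_genes(
    vector: SyndromeScoreVector | Mapping[str, float], gmap: GenePhenotypeMap
) -> dict[str, float]:
    """Gene score = max over its linked syndromes present in the vector.

    Genes none of whose syndromes are scored are absent from the output
    ("unscored" stays distinguishable from "scored 0"); syndromes with
    no gene link contribute nothing and are counted in a debug log.
    """
    scores = vector.scores if isinstance(vector, SyndromeScoreVector) else dict(vector)
    out: dict[str, float] = {}
    n_unmapped = 0
    for syndrome, score in scores.items():
        genes = gmap.syndrome_to_genes.get(syndrome)
        if not genes:
            n_unmapped += 1
            continue
        for g in genes:
            prev = out.get(g)
            if prev is None or score > prev:
                out[g] = score
    if n_unmapped:
        logger.debug("%d scored syndrome(s) had no gene mapping", n_unmapped)
    return out
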