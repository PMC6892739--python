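"""Variant-level deleteriousness handling: VCF ingestion, rare-disease
filtering, per-gene max reduction, and causal-variant spike-in.

The benchmark emulates exome analysis for a case whose sequencing data
is unavailable: the causal variant's deleteriousness score is spiked
into a background exome (a per-gene max-score map from a healthy
individual), and per gene the maximum score among surviving variants is
kept regardless of genotype — a sensitivity-first heuristic that also
covers compound-heterozygous cases whose second hit scores low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam

logger = logging.getLogger(__name__)

DEFAULT_ANNOTATION_KEYS = {
    "deleteriousness": "CADD_PHRED",
    "gene": "GENE",
    "allele_freq": "AF",
    "consequence": "CSQ_CLASS",
}

#: Consequence classes kept by default: protein-altering coding classes.
DEFAULT_CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "canonical_splice",
    }
)


@dataclass
class VariantRecord:
    """One ALT allele of a VCF site with its annotations (1-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    deleteriousness: float
    allele_freq: float
    consequence: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError(f"allele_freq must be in [0,1], got {self.allele_freq}")


@dataclass
class FilterConfig:
    """Parameterized rare-disease variant filter.

    Reduces trio-style filtering to three predicates: population allele
    frequency at most ``max_allele_freq``, consequence class in
    ``allowed_consequences``, and an optional deleteriousness floor.
    Genotype/inheritance logic is deliberately not modeled.
    """

    max_allele_freq: float = 0.01
    allowed_consequences: frozenset[str] = DEFAULT_CONSEQUENCES
    min_deleteriousness: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_allele_freq <= 1.0):
            raise ValueError("max_allele_freq must be in [0,1]")
        self.allowed_consequences = frozenset(self.allowed_consequences)

    def keeps(self, rec: VariantRecord) -> bool:
        return (
            rec.allele_freq <= self.max_allele_freq
            and rec.consequence in self.allowed_consequences
            and (
                self.min_deleteriousness is None
                or rec.deleteriousness >= self.min_deleteriousness
            )
        )


@dataclass
class GeneMaxScoreMap:
    """gene -> max deleteriousness among its surviving variants."""

    scores: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores

    def __len__(self) -> int:
        return len(self.scores)


def _per_alt(value, i: int, n_alts: int):
    """INFO values may be scalar or per-ALT tuples (Number=A)."""
    if isinstance(value, (tuple, list)):
        return value[i] if len(value) == n_alts else value[0]
    return value


def read_scored_variants(
    vcf_path: str | Path,
    annotation_keys: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read annotated variants from a VCF 4.x file.

    Multi-allelic sites are split into one record per ALT.  Records
    missing the deleteriousness key are skipped and counted in a logged
    warning; a missing allele-frequency annotation is treated as 0
    (assume rare).
    """
    keys = dict(DEFAULT_ANNOTATION_KEYS)
    keys.update(annotation_keys or {})
    records: list[VariantRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for site in vcf:
            alts = site.alts or ()
            info = dict(site.info)
            if keys["deleteriousness"] not in info:
                n_skipped += len(alts)
                continue
            for i, alt in enumerate(alts):
                dele = _per_alt(info[keys["deleteriousness"]], i, len(alts))
                gene = _per_alt(info.get(keys["gene"], ""), i, len(alts))
                af = _per_alt(info.get(keys["allele_freq"], 0.0), i, len(alts))
                csq = _per_alt(info.get(keys["consequence"], ""), i, len(alts))
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=str(alt),
                        gene=str(gene),
                        deleteriousness=float(dele),
                        allele_freq=float(af if af is not None else 0.0),
                        consequence=str(csq),
                    )
                )
    if n_skipped:
        logger.warning(
            "%s: skipped %d allele record(s) lacking INFO/%s",
            vcf_path, n_skipped, keys["deleteriousness"],
        )
    return records


def filter_variants(
    records: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Keep records passing the frequency/consequence/score predicates (order preserved)."""
    config = config or FilterConfig()
    return [r for r in records if config.keeps(r)]


def gene_max_score(records: Iterable[VariantRecord]) -> GeneMaxScoreMap:
    """Per gene, the maximum deleteriousness among its (filtered) variants."""
    scores: dict[str, float] = {}
    for r in records:
        prev = scores.get(r.gene)
        if prev is None or r.deleteriousness > prev:
            scores[r.gene] = r.deleteriousness
    return GeneMaxScoreMap(scores)


def spike_in(
    background: GeneMaxScoreMap, causal_gene: str, causal_score: float
) -> GeneMaxScoreMap:
    """Insert the causal variant's score into a background exome.

    Pure function: the background map is not modified.  The causal gene
    keeps the larger of its background score and ``causal_score``, so a
    spike-in never lowers any gene's score.
    """
    if causal_score < 0:
        raise ValueError("causal_score must be >= 0")
    scores = dict(background.scores)
    scores[causal_gene] = max(scores.get(causal_gene, 0.0), causal_score)
    return GeneMaxScoreMap(scores)


def write_gene_scores(scores: GeneMaxScoreMap, path: str | Path) -> None:
    """Serialize a gene score map as 2-column TSV (gene, score)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in sorted(scores.scores):
            fh.write(f"{gene}\t{scores.scores[gene]!r}\n")


def read_gene_scores(path: str | Path) -> GeneMaxScoreMap:
    scores = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, value = line.rstrip("\n").split("\t")
            scores[gene] = float(value)
    return GeneMaxScoreMap(scores)
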