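"""Core domain types and readers/writers for case and score files.

A *case* is one patient: clinical features as HPO terms, an optional
facial-gestalt similarity vector over syndromes, the molecularly
confirmed causal gene and the deleteriousness score of its causal
variant.  A *gene score table* holds, per candidate gene of one case,
the five evidence scores the classifier consumes plus the Boolean
causal label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

SCORE_COLUMNS = ("cadd", "gestalt", "feature_match", "phenomizer", "boqa")


class CohortFormatError(ValueError):
    """A case file could not be parsed or violated an invariant."""


@dataclass
class CaseRecord:
    """One patient of the cohort.

    Parameters
    ----------
    case_id : unique identifier.
    hpo_terms : nonempty set of HPO term IDs (``HP:NNNNNNN``).
    diagnosis_id : syndrome identifier (OMIM-style string).
    causal_gene : symbol of the molecularly confirmed disease gene.
    causal_variant_score : deleteriousness of the causal variant on the
        CADD-PHRED scale (nonnegative).
    gestalt_scores : syndrome_id -> nonnegative similarity; may be empty
        for a case without a usable photo.
    ethnicity : free background tag (e.g. ``"EUR"``, ``"AFR"``).
    """

    case_id: str
    hpo_terms: set[str]
    diagnosis_id: str
    causal_gene: str
    causal_variant_score: float
    gestalt_scores: dict[str, float] = field(default_factory=dict)
    ethnicity: str = ""

    def __post_init__(self) -> None:
        self.causal_gene = self.causal_gene.strip()
        self.hpo_terms = set(self.hpo_terms)
        violations = self.validate()
        if violations:
            raise CohortFormatError(
                f"case {self.case_id!r}: " + "; ".join(violations)
            )

    def validate(self) -> list[str]:
        v = []
        if not self.hpo_terms:
            v.append("hpo_terms must be nonempty")
        if not self.causal_gene:
            v.append("causal_gene must be nonempty")
        if not (self.causal_variant_score >= 0):
            v.append("causal_variant_score must be >= 0")
        if any(s < 0 for s in self.gestalt_scores.values()):
            v.append("gestalt_scores must be nonnegative")
        return v

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "hpo_terms": sorted(self.hpo_terms),
            "diagnosis_id": self.diagnosis_id,
            "causal_gene": self.causal_gene,
            "causal_variant_score": self.causal_variant_score,
            "gestalt_scores": dict(sorted(self.gestalt_scores.items())),
            "ethnicity": self.ethnicity,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CaseRecord":
        try:
            return cls(
                case_id=str(d["case_id"]),
                hpo_terms=set(d["hpo_terms"]),
                diagnosis_id=str(d["diagnosis_id"]),
                causal_gene=str(d["causal_gene"]),
                causal_variant_score=float(d["causal_variant_score"]),
                gestalt_scores={
                    str(k): float(v) for k, v in dict(d.get("gestalt_scores") or {}).items()
                },
                ethnicity=str(d.get("ethnicity", "")),
            )
        except KeyError as e:
            raise CohortFormatError(f"missing field {e.args[0]!r} in case record") from e


@dataclass
class GeneScoreRow:
    """One candidate gene with its five evidence scores and causal label."""

    gene: str
    cadd: float
    gestalt: float
    feature_match: float
    phenomizer: float
    boqa: float
    label: bool

    def __post_init__(self) -> None:
        self.gene = self.gene.strip()

    def scores(self) -> tuple[float, ...]:
        return tuple(getattr(self, c) for c in SCORE_COLUMNS)


@dataclass
class GeneScoreTable:
    """Per-case table: one row per candidate gene, five score columns."""

    case_id: str
    rows: list[GeneScoreRow]

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "rows": [
                {
                    "gene": r.gene,
                    **{c: getattr(r, c) for c in SCORE_COLUMNS},
                    "label": r.label,
                }
                for r in self.rows
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneScoreTable":
        return cls(
            case_id=str(d["case_id"]),
            rows=[
                GeneScoreRow(
                    gene=str(r["gene"]),
                    **{c: float(r[c]) for c in SCORE_COLUMNS},
                    label=bool(r["label"]),
                )
                for r in d["rows"]
            ],
        )


@dataclass
class Cohort:
    """A list of cases plus, optionally, their assembled score tables."""

    cases: list[CaseRecord]
    tables: dict[str, GeneScoreTable] | None = None

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate case_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.cases)


def validate_table(table: GeneScoreTable) -> list[str]:
    """Return all invariant violations of *table* (empty list = valid)."""
    violations = []
    genes = [r.gene for r in table.rows]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        violations.append(f"duplicate gene symbol(s): {dupes}")
    n_true = sum(r.label for r in table.rows)
    if n_true != 1:
        violations.append(f"expected exactly one causal label, found {n_true}")
    for r in table.rows:
        if not all(math.isfinite(s) for s in r.scores()):
            violations.append(f"non-finite score in row for gene {r.gene!r}")
    return violations


def _iter_case_dicts(path: Path) -> Iterable[tuple[Path, dict]]:
    if path.is_dir():
        for f in sorted(path.glob("*.json")):
            with open(f, encoding="utf-8") as fh:
                try:
                    yield f, json.load(fh)
                except json.JSONDecodeError as e:
                    raise CohortFormatError(f"malformed JSON in {f}: {e}") from e
    else:
        # single file: either a JSON array or JSON-lines
        text = path.read_text(encoding="utf-8")
        stripped = text.lstrip()
        if stripped.startswith("["):
            for d in json.loads(text):
                yield path, d
        else:
            for ln, line in enumerate(text.splitlines(), 1):
                if not line.strip():
                    continue
                try:
                    yield path, json.loads(line)
                except json.JSONDecodeError as e:
                    raise CohortFormatError(
                        f"malformed JSON on line {ln} of {path}: {e}"
                    ) from e


def load_cohort(path: str | Path) -> Cohort:
    """Load a cohort from a directory of per-case JSON files or one JSON-lines file.

    Raises :class:`CohortFormatError` naming the offending file/case on
    malformed JSON, invariant violations, or duplicate case ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cases = []
    for src, d in _iter_case_dicts(path):
        try:
            cases.append(CaseRecord.from_dict(d))
        except CohortFormatError as e:
            raise CohortFormatError(f"{src}: {e}") from e
    return Cohort(cases=cases)


def save_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write one JSON file per case into *directory* (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for case in cohort.cases:
        with open(directory / f"{case.case_id}.json", "w", encoding="utf-8") as fh:
            json.dump(case.to_dict(), fh, indent=1)
            fh.write("\n")


def save_tables(tables: Mapping[str, GeneScoreTable], path: str | Path) -> None:
    """Write assembled score tables as one JSON document keyed by case id."""
    payload = {cid: t.to_dict() for cid, t in sorted(tables.items())}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_tables(path: str | Path) -> dict[str, GeneScoreTable]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {cid: GeneScoreTable.from_dict(d) for cid, d in payload.items()}


def write_ranked_output(result, path: str | Path) -> None:
    """Write a :class:`~pediascore.classifier.RankedResult` as a TSV.

    Columns: gene, pedia_score, rank, then the five input scores; rows
    ordered by rank.  Full float precision (``repr``) is kept so a
    re-read reproduces the ranking exactly.
    """
    if not result.entries:
        raise ValueError("empty ranked result")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tpedia_score\trank\t" + "\t".join(SCORE_COLUMNS) + "\n")
        for e in result.entries:
            fh.write(
                f"{e.gene}\t{e.pedia_score!r}\t{e.rank}\t"
                + "\t".join(repr(s) for s in e.scores)
                + "\n"
            )
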