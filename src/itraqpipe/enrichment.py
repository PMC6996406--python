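"""Protein-class over-representation testing.

Given an annotated reference proteome (how many of the organism's proteins
belong to each protein class) and an input list of identified proteins, each
class is scored by its expected membership under random sampling,
``expected = input_size * reference_count / reference_total``, the fold
enrichment ``observed / expected`` with an over (+) / under (-) direction,
and a one-sided binomial tail p-value, Bonferroni-corrected over the classes
actually tested.  This mirrors the classic PANTHER-style over-representation
test; Fisher's exact test is available as an alternative test family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from scipy import stats

__all__ = [
    "AnnotationTable",
    "EnrichmentRow",
    "expected_count",
    "fold_enrichment",
    "binomial_pvalue",
    "fisher_pvalue",
    "overrepresentation_test",
    "bonferroni_filter",
    "read_annotation_table",
    "write_enrichment_table",
    "load_llcpk1_example",
]


@dataclass(frozen=True)
class AnnotationTable:
    """Reference protein classes: class id -> (name, reference count)."""

    classes: dict[str, tuple[str, int]]
    reference_total: int

    def __post_init__(self) -> None:
        if self.reference_total <= 0:
            raise ValueError("reference_total must be positive")
        for cid, (_, count) in self.classes.items():
            if not 0 <= count <= self.reference_total:
                raise ValueError(
                    f"class {cid}: reference count {count} outside "
                    f"[0, {self.reference_total}]"
                )


@dataclass(frozen=True)
class EnrichmentRow:
    class_id: str
    class_name: str
    reference_count: int
    observed: int
    expected: float
    direction: str  # "+" over-represented, "-" under-represented
    fold_enrichment: float
    p_raw: float
    p_corrected: float | None = None


def expected_count(reference_count: int, reference_total: int, input_size: int) -> float:
    """Expected class members among ``input_size`` random reference proteins."""
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    if not 0 <= reference_count <= reference_total:
        raise ValueError("reference_count must lie in [0, reference_total]")
    if input_size < 0:
        raise ValueError("input_size must be non-negative")
    return input_size * reference_count / reference_total


def fold_enrichment(observed: int, expected: float) -> tuple[str, float]:
    """(direction, observed/expected); direction is '+' iff the class is over-represented."""
    if expected <= 0:
        raise ValueError("expected must be positive (empty classes are not testable)")
    fold = observed / expected
    return ("+" if fold > 1 else "-", fold)


def binomial_pvalue(observed: int, input_size: int, p: float, direction: str) -> float:
    """One-sided binomial tail for class membership among the input proteins.

    ``P(X >= observed)`` for direction '+', ``P(X <= observed)`` for '-',
    with ``X ~ Binomial(input_size, p)`` and ``p`` the class's reference
    frequency.
    """
    if not 0 <= observed <= input_size:
        raise ValueError("observed must lie in [0, input_size]")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    if direction == "+":
        return float(stats.binom.sf(observed - 1, input_size, p))
    if direction == "-":
        return float(stats.binom.cdf(observed, input_size, p))
    raise ValueError(f"direction must be '+' or '-', got {direction!r}")


def fisher_pvalue(
    observed: int,
    input_size: int,
    reference_count: int,
    reference_total: int,
    direction: str,
) -> float:
    """One-sided Fisher exact tail on the 2x2 membership table."""
    table = [
        [observed, input_size - observed],
        [reference_count - observed, (reference_total - reference_count) - (input_size - observed)],
    ]
    alternative = "greater" if direction == "+" else "less"
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def overrepresentation_test(
    annotation: AnnotationTable,
    observed_counts: Mapping[str, int],
    input_size: int,
    test: str = "binomial",
    bonferroni_m: int | None = None,
) -> list[EnrichmentRow]:
    """Score every class with at least one observed protein.

    ``observed_counts`` maps class id to the number of input proteins in the
    class.  The Bonferroni multiplier defaults to the number of classes
    tested (those with >= 1 input protein); rows come back sorted by
    descending fold enrichment.
    """
    if test not in {"binomial", "fisher"}:
        raise ValueError(f"unknown test family {test!r}")
    tested = [cid for cid, n in observed_counts.items() if n > 0]
    m = bonferroni_m if bonferroni_m is not None else len(tested)
    if m < len(tested):
        raise ValueError("Bonferroni multiplier smaller than the number of tests")
    rows: list[EnrichmentRow] = []
    for cid in tested:
        if cid not in annotation.classes:
            raise KeyError(f"class {cid!r} absent from the annotation table")
        name, reference_count = annotation.classes[cid]
        observed = int(observed_counts[cid])
        expected = expected_count(reference_count, annotation.reference_total, input_size)
        direction, fold = fold_enrichment(observed, expected)
        p_class = reference_count / annotation.reference_total
        if test == "binomial":
            p_raw = binomial_pvalue(observed, input_size, p_class, direction)
        else:
            p_raw = fisher_pvalue(
                observed, input_size, reference_count, annotation.reference_total, direction
            )
        rows.append(
            EnrichmentRow(
                class_id=cid,
                class_name=name,
                reference_count=reference_count,
                observed=observed,
                expected=expected,
                direction=direction,
                fold_enrichment=fold,
                p_raw=p_raw,
                p_corrected=min(1.0, m * p_raw),
            )
        )
    rows.sort(key=lambda r: (-r.fold_enrichment, r.class_id))
    return rows


def bonferroni_filter(
    rows: Sequence[EnrichmentRow], alpha: float = 0.05, m: int | None = None
) -> list[EnrichmentRow]:
    """Keep rows whose Bonferroni-corrected p-value is strictly below alpha.

    When ``m`` is given, corrected p-values are recomputed as
    ``min(1, m * p_raw)``; otherwise the rows' stored corrections are used.
    """
    if m is not None:
        if m < len(rows):
            raise ValueError("Bonferroni multiplier smaller than the number of rows")
        rows = [replace(r, p_corrected=min(1.0, m * r.p_raw)) for r in rows]
    out = []
    for row in rows:
        if row.p_corrected is None:
            raise ValueError(f"row {row.class_id} has no corrected p-value")
        if row.p_corrected < alpha:
            out.append(row)
    return out


# ---------------------------------------------------------------------------
# I/O

def read_annotation_table(path: str | Path) -> tuple[AnnotationTable, dict[str, int]]:
    """Read a class table TSV.

    Header comment lines carry ``# reference_total=N`` (and optionally
    ``# input_total=N``); data columns are ``class_id  class_name
    reference_count  [observed]``.  Returns the annotation plus the observed
    counts column (empty mapping when the column is absent).
    """
    reference_total: int | None = None
    classes: dict[str, tuple[str, int]] = {}
    observed: dict[str, int] = {}
    header: list[str] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("reference_total="):
                reference_total = int(body.split("=", 1)[1])
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            continue
        row = dict(zip(header, cells))
        cid = row["class_id"]
        classes[cid] = (row.get("class_name", cid), int(row["reference_count"]))
        if "observed" in row and row["observed"] != "":
            observed[cid] = int(row["observed"])
    if reference_total is None:
        raise ValueError(f"{path}: missing '# reference_total=' header")
    return AnnotationTable(classes=classes, reference_total=reference_total), observed


def write_enrichment_table(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    """Write a class-enrichment TSV, report columns rounded to 2 d.p."""
    lines = [
        "class_id\tclass_name\treference_count\tobserved\texpected\t"
        "direction\tfold_enrichment\tp_raw\tp_corrected"
    ]
    for r in rows:
        corrected = "" if r.p_corrected is None else f"{r.p_corrected:.3g}"
        lines.append(
            f"{r.class_id}\t{r.class_name}\t{r.reference_count}\t{r.observed}\t"
            f"{r.expected:.2f}\t{r.direction}\t{r.fold_enrichment:.2f}\t"
            f"{r.p_raw:.3g}\t{corrected}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_llcpk1_example() -> tuple[AnnotationTable, dict[str, int], int]:
    """Packaged example: PANTHER protein-class counts for a porcine
    proximal-tubule (LLC PK-1) proteome of 128 classified proteins against
    the 21,324-protein Sus scrofa reference list.

    Returns (annotation, observed counts per class, input size).
    """
    ref = resources.files("itraqpipe.data").joinpath("llcpk1_panther_classes.tsv")
    input_total = 128
    for line in ref.read_text().splitlines():
        if line.startswith("#") and "input_total=" in line:
            input_total = int(line.split("input_total=")[1].strip())
    with resources.as_file(ref) as path:
        annotation, observed = read_annotation_table(path)
    return annotation, observed, input_total
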