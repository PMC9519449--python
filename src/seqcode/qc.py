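"""Eligibility of a genome to serve as a nomenclatural type.

Two tiers of criteria are evaluated, mirroring the registry's validation
checklist:

Required (blockers):
  * MAGs and SAGs: completeness strictly > 90 % and contamination strictly
    < 5 % (CheckM-style estimates, consumed as inputs, never recomputed).
  * Isolates: read coverage >= 10x.
  * The type assembly must be deposited in the INSDC databases; raw reads
    must also be deposited unless the name was effectively published before
    1 January 2023 (grandfather clause — the check is then not applicable).

Recommended (warnings, never blockers):
  * 16S rRNA gene > 75 % complete and passing chimaera checks.
  * Agreement between genome-based and 16S-based taxonomic assignments.
  * > 80 % of the 20 standard tRNA isoacceptor types present (i.e. >= 17).
  * Genome integrity: fewer than 100 contigs, N50 > 25 kb, largest contig
    > 100 kb.
  * MAG/SAG read coverage >= 10x.

Equality at a strict bound fails: a MAG at exactly 90 % completeness is not
eligible, and 16 of 20 tRNAs (exactly 80 %) does not satisfy "> 80 %".
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .assembly import AssemblyStats

__all__ = [
    "GenomeCategory",
    "CheckStatus",
    "QualityMetrics",
    "CheckResult",
    "QCReport",
    "evaluate_required",
    "evaluate_recommended",
    "qc_report",
    "read_metrics_tsv",
    "RAW_READS_GRANDFATHER_DATE",
]

#: Names effectively published before this date are exempt from the
#: raw-read deposition requirement.
RAW_READS_GRANDFATHER_DATE = _dt.date(2023, 1, 1)

TRNA_TYPES_TOTAL = 20


class GenomeCategory(str, Enum):
    ISOLATE = "isolate"
    MAG = "MAG"
    SAG = "SAG"


class CheckStatus(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"
    NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class QualityMetrics:
    """Externally computed quality numbers for one genome.

    ``completeness_pct`` and ``contamination_pct`` are marker-gene estimates
    (e.g. CheckM); ``trna_count`` counts distinct standard isoacceptor types
    out of 20; ``ssu_completeness_pct`` is the fraction of a full-length 16S
    gene recovered.  ``estimator`` records the tool that produced the
    completeness/contamination numbers as free text.
    """

    category: GenomeCategory
    completeness_pct: Optional[float] = None
    contamination_pct: Optional[float] = None
    coverage_x: Optional[float] = None
    trna_count: Optional[int] = None
    ssu_completeness_pct: Optional[float] = None
    ssu_chimera_pass: Optional[bool] = None
    taxonomy_concordant: Optional[bool] = None
    raw_reads_deposited: bool = False
    assembly_deposited: bool = False
    effective_publication_date: Optional[_dt.date] = None
    estimator: Optional[str] = None

    def __post_init__(self) -> None:
        for attr in ("completeness_pct", "contamination_pct", "ssu_completeness_pct"):
            val = getattr(self, attr)
            if val is not None and not 0.0 <= val <= 100.0:
                raise ValueError(f"{attr} must be within [0, 100], got {val}")
        if self.coverage_x is not None and self.coverage_x < 0:
            raise ValueError(f"coverage_x must be >= 0, got {self.coverage_x}")
        if self.trna_count is not None and not 0 <= self.trna_count <= TRNA_TYPES_TOTAL:
            raise ValueError(
                f"trna_count must be within [0, {TRNA_TYPES_TOTAL}], got {self.trna_count}"
            )


@dataclass(frozen=True)
class CheckResult:
    check_id: str
    threshold: str
    observed: str
    status: CheckStatus
    note: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.status is CheckStatus.PASS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["status"] = self.status.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CheckResult":
        return cls(
            check_id=d["check_id"],
            threshold=d["threshold"],
            observed=d["observed"],
            status=CheckStatus(d["status"]),
            note=d.get("note"),
        )


@dataclass(frozen=True)
class QCReport:
    """Combined required/recommended verdict for one genome.

    ``eligible_as_type`` is true iff every applicable required check passes.
    Recommended failures are surfaced as warnings and never affect
    eligibility.  ``notes`` carries free text, e.g. author-justified
    exceptions for lower data quality.
    """

    required_checks: tuple[CheckResult, ...]
    recommended_checks: tuple[CheckResult, ...]
    eligible_as_type: bool
    notes: tuple[str, ...] = ()

    @property
    def warnings(self) -> tuple[CheckResult, ...]:
        return tuple(c for c in self.recommended_checks if c.status is CheckStatus.FAIL)

    def to_dict(self) -> dict:
        return {
            "required_checks": [c.to_dict() for c in self.required_checks],
            "recommended_checks": [c.to_dict() for c in self.recommended_checks],
            "eligible_as_type": self.eligible_as_type,
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCReport":
        return cls(
            required_checks=tuple(CheckResult.from_dict(c) for c in d["required_checks"]),
            recommended_checks=tuple(
                CheckResult.from_dict(c) for c in d["recommended_checks"]
            ),
            eligible_as_type=bool(d["eligible_as_type"]),
            notes=tuple(d.get("notes", [])),
        )


def _fmt(value) -> str:
    if value is None:
        return "absent"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def evaluate_required(
    stats: Optional[AssemblyStats], metrics: QualityMetrics
) -> list[CheckResult]:
    """Evaluate the blocking criteria for type eligibility.

    Missing completeness/contamination for a MAG/SAG (or missing coverage for
    an isolate) fails with a "metric absent" note rather than silently
    passing.
    """
    checks: list[CheckResult] = []

    if metrics.category in (GenomeCategory.MAG, GenomeCategory.SAG):
        if metrics.completeness_pct is None:
            checks.append(
                CheckResult("completeness", ">90%", "absent", CheckStatus.FAIL,
                            "metric absent")
            )
        else:
            ok = metrics.completeness_pct > 90.0
            checks.append(
                CheckResult("completeness", ">90%", _fmt(metrics.completeness_pct),
                            CheckStatus.PASS if ok else CheckStatus.FAIL)
            )
        if metrics.contamination_pct is None:
            checks.append(
                CheckResult("contamination", "<5%", "absent", CheckStatus.FAIL,
                            "metric absent")
            )
        else:
            ok = metrics.contamination_pct < 5.0
            checks.append(
                CheckResult("contamination", "<5%", _fmt(metrics.contamination_pct),
                            CheckStatus.PASS if ok else CheckStatus.FAIL)
            )
    else:  # isolate
        if metrics.coverage_x is None:
            checks.append(
                CheckResult("isolate_coverage", ">=10x", "absent", CheckStatus.FAIL,
                            "metric absent")
            )
        else:
            ok = metrics.coverage_x >= 10.0
            checks.append(
                CheckResult("isolate_coverage", ">=10x", _fmt(metrics.coverage_x),
                            CheckStatus.PASS if ok else CheckStatus.FAIL)
            )

    checks.append(
        CheckResult(
            "assembly_deposited", "assembly in INSDC",
            _fmt(metrics.assembly_deposited),
            CheckStatus.PASS if metrics.assembly_deposited else CheckStatus.FAIL,
        )
    )

    grandfathered = (
        metrics.effective_publication_date is not None
        and metrics.effective_publication_date < RAW_READS_GRANDFATHER_DATE
    )
    if grandfathered:
        checks.append(
            CheckResult(
                "raw_reads_deposited", "raw reads in INSDC",
                _fmt(metrics.raw_reads_deposited),
                CheckStatus.NOT_APPLICABLE,
                f"effectively published {metrics.effective_publication_date.isoformat()}, "
                f"before {RAW_READS_GRANDFATHER_DATE.isoformat()}",
            )
        )
    else:
        checks.append(
            CheckResult(
                "raw_reads_deposited", "raw reads in INSDC",
                _fmt(metrics.raw_reads_deposited),
                CheckStatus.PASS if metrics.raw_reads_deposited else CheckStatus.FAIL,
            )
        )
    return checks


def evaluate_recommended(
    stats: Optional[AssemblyStats], metrics: QualityMetrics
) -> list[CheckResult]:
    """Evaluate the advisory criteria; absent numeric metrics yield
    not-evaluated entries, absent boolean confirmations warn."""
    checks: list[CheckResult] = []

    # 16S: one combined entry when no 16S data exists at all.
    if metrics.ssu_completeness_pct is None and metrics.ssu_chimera_pass is None:
        checks.append(
            CheckResult("ssu_rrna", ">75% complete, passes chimaera checks",
                        "absent", CheckStatus.NOT_EVALUATED)
        )
    else:
        complete_ok = (
            metrics.ssu_completeness_pct is not None
            and metrics.ssu_completeness_pct > 75.0
        )
        chimera_ok = metrics.ssu_chimera_pass is True
        observed = (
            f"completeness {_fmt(metrics.ssu_completeness_pct)}, "
            f"chimaera check {_fmt(metrics.ssu_chimera_pass)}"
        )
        checks.append(
            CheckResult("ssu_rrna", ">75% complete, passes chimaera checks",
                        observed,
                        CheckStatus.PASS if complete_ok and chimera_ok else CheckStatus.FAIL)
        )

    if metrics.taxonomy_concordant is None:
        checks.append(
            CheckResult("taxonomy_concordance",
                        "genome and 16S taxonomic assignments agree",
                        "absent", CheckStatus.FAIL, "concordance not confirmed")
        )
    else:
        checks.append(
            CheckResult("taxonomy_concordance",
                        "genome and 16S taxonomic assignments agree",
                        _fmt(metrics.taxonomy_concordant),
                        CheckStatus.PASS if metrics.taxonomy_concordant else CheckStatus.FAIL)
        )

    if metrics.trna_count is None:
        checks.append(
            CheckResult("trna_set", ">80% of 20 tRNA types", "absent",
                        CheckStatus.NOT_EVALUATED)
        )
    else:
        # >80% of 20 means at least 17; exactly 16 (80%) does not qualify
        ok = metrics.trna_count > 16
        checks.append(
            CheckResult("trna_set", ">80% of 20 tRNA types",
                        f"{metrics.trna_count}/20",
                        CheckStatus.PASS if ok else CheckStatus.FAIL)
        )

    if stats is None:
        checks.append(
            CheckResult("genome_integrity",
                        "contigs <100; N50 >25 kb; largest contig >100 kb",
                        "no assembly statistics", CheckStatus.NOT_EVALUATED)
        )
    else:
        checks.append(
            CheckResult("contig_count", "<100", str(stats.n_contigs),
                        CheckStatus.PASS if stats.n_contigs < 100 else CheckStatus.FAIL)
        )
        checks.append(
            CheckResult("n50", ">25 kb", str(stats.n50),
                        CheckStatus.PASS if stats.n50 > 25_000 else CheckStatus.FAIL)
        )
        checks.append(
            CheckResult("largest_contig", ">100 kb", str(stats.largest_contig),
                        CheckStatus.PASS if stats.largest_contig > 100_000 else CheckStatus.FAIL)
        )

    if metrics.category in (GenomeCategory.MAG, GenomeCategory.SAG):
        if metrics.coverage_x is None:
            checks.append(
                CheckResult("coverage", ">=10x", "absent", CheckStatus.NOT_EVALUATED)
            )
        else:
            checks.append(
                CheckResult("coverage", ">=10x", _fmt(metrics.coverage_x),
                            CheckStatus.PASS if metrics.coverage_x >= 10.0 else CheckStatus.FAIL)
            )
    else:
        checks.append(
            CheckResult("coverage", ">=10x (MAG/SAG)", _fmt(metrics.coverage_x),
                        CheckStatus.NOT_APPLICABLE, "isolate coverage is a required check")
        )
    return checks


def qc_report(
    stats: Optional[AssemblyStats],
    metrics: QualityMetrics,
    notes: tuple[str, ...] | list[str] = (),
) -> QCReport:
    """Combine required and recommended evaluations into a QCReport."""
    required = evaluate_required(stats, metrics)
    recommended = evaluate_recommended(stats, metrics)
    eligible = all(
        c.status in (CheckStatus.PASS, CheckStatus.NOT_APPLICABLE) for c in required
    )
    return QCReport(
        required_checks=tuple(required),
        recommended_checks=tuple(recommended),
        eligible_as_type=eligible,
        notes=tuple(notes),
    )


_BOOL_STRINGS = {
    "true": True, "yes": True, "1": True,
    "false": False, "no": False, "0": False,
}


def _coerce_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    return _BOOL_STRINGS[str(value).strip().lower()]


def read_metrics_tsv(path: Union[str, Path]) -> dict[str, QualityMetrics]:
    """Read a batch metrics table: one genome per row, columns named after
    :class:`QualityMetrics` fields plus a leading ``genome_id``."""
    df = pd.read_csv(path, sep="\t")
    if "genome_id" not in df.columns or "category" not in df.columns:
        raise ValueError("metrics TSV needs 'genome_id' and 'category' columns")
    out: dict[str, QualityMetrics] = {}
    for _, row in df.iterrows():
        def get(col, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        date = get("effective_publication_date", str)
        out[str(row["genome_id"])] = QualityMetrics(
            category=GenomeCategory(str(row["category"])),
            completeness_pct=get("completeness_pct"),
            contamination_pct=get("contamination_pct"),
            coverage_x=get("coverage_x"),
            trna_count=get("trna_count", int),
            ssu_completeness_pct=get("ssu_completeness_pct"),
            ssu_chimera_pass=_coerce_bool(row.get("ssu_chimera_pass")),
            taxonomy_concordant=_coerce_bool(row.get("taxonomy_concordant")),
            raw_reads_deposited=bool(_coerce_bool(row.get("raw_reads_deposited")) or False),
            assembly_deposited=bool(_coerce_bool(row.get("assembly_deposited")) or False),
            effective_publication_date=_dt.date.fromisoformat(date) if date else None,
            estimator=get("estimator", str),
        )
    return out
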