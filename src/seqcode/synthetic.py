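"""Seeded generators for assemblies, quality metrics and registry fixtures.

Everything every other module consumes can be generated here offline and
reproducibly: FASTA assemblies with a target GC content and contig-length
law, point-mutated copies for ANI parameter recovery (substitution-only, so
the expected ANI of a mutated copy is exactly 100·(1 − rate)), random
quality-metric vectors for threshold testing, and populated registries with
planted homonym pairs, *Candidatus* intake sets and known priority orderings
accompanied by an answer key.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .assembly import AssemblyRecord
from .nomenclature import Rank, TaxonName
from .qc import GenomeCategory, QCReport, QualityMetrics, qc_report
from .registry import (
    EntryStatus,
    ExternalName,
    Registry,
    RegistryEntry,
    TypeDesignation,
    TypeKind,
)

__all__ = [
    "SynthSpec",
    "generate_assembly",
    "mutate_genome",
    "random_metrics",
    "passing_metrics",
    "generate_registry_fixture",
    "RegistryAnswerKey",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic assembly.

    ``length_law`` is either ``lognormal`` (parameters: mean and sigma of
    log contig length, in log-bases) or ``fixed`` (parameters: the exact
    contig lengths).  ``gc_target`` is the expected G+C percentage.
    """

    n_contigs: int
    length_law: Literal["lognormal", "fixed"] = "lognormal"
    length_params: tuple[float, ...] = (10.5, 0.8)
    gc_target: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if not 0.0 <= self.gc_target <= 100.0:
            raise ValueError("gc_target must be within [0, 100]")
        if self.length_law == "fixed":
            if len(self.length_params) != self.n_contigs:
                raise ValueError(
                    "fixed length law needs exactly n_contigs lengths"
                )
            if any(l < 1 for l in self.length_params):
                raise ValueError("contig lengths must be positive")
        elif self.length_law == "lognormal":
            if len(self.length_params) != 2 or self.length_params[1] <= 0:
                raise ValueError(
                    "lognormal law needs (mean, sigma) with sigma > 0"
                )
        else:
            raise ValueError(f"unknown length law {self.length_law!r}")


def _contig_lengths(spec: SynthSpec, rng: np.random.Generator) -> list[int]:
    if spec.length_law == "fixed":
        return [int(l) for l in spec.length_params]
    mean, sigma = spec.length_params
    lengths = rng.lognormal(mean, sigma, size=spec.n_contigs)
    return [max(100, int(round(l))) for l in lengths]


def generate_assembly(spec: SynthSpec) -> AssemblyRecord:
    """Generate a random assembly, reproducible for a fixed seed.

    Bases are drawn independently with P(G) = P(C) = gc_target/200, so for
    total lengths of 100 kb and more the realized GC is within about one
    percentage point of the target.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _contig_lengths(spec, rng)
    gc = spec.gc_target / 100.0
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = []
    for i, length in enumerate(lengths, start=1):
        draws = rng.choice(4, size=length, p=probs)
        seq = _BASES[draws].tobytes().decode("ascii")
        contigs.append((f"contig_{i}", seq))
    return AssemblyRecord.from_pairs(contigs)


def mutate_genome(
    assembly: AssemblyRecord, substitution_rate: float, seed: int
) -> AssemblyRecord:
    """Substitute each base independently with the given probability,
    always to a *different* base; contig structure is preserved.

    With substitutions only (no indels), the expected nucleotide identity of
    the mutated copy against the original is exactly 1 − rate.
    """
    if not 0.0 <= substitution_rate <= 0.3:
        raise ValueError(
            f"substitution_rate must be within [0, 0.3], got {substitution_rate}"
        )
    rng = np.random.default_rng(seed)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    contigs = []
    for name, seq in assembly.contigs:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = code[raw]
        mask = (rng.random(len(codes)) < substitution_rate) & (codes != 255)
        # shift by 1..3 mod 4 guarantees a different base
        shifts = rng.integers(1, 4, size=len(codes)).astype(np.uint8)
        mutated = codes.copy()
        mutated[mask] = (codes[mask] + shifts[mask]) % 4
        out = raw.copy()
        out[mask] = _BASES[mutated[mask]]
        contigs.append((name, out.tobytes().decode("ascii")))
    return AssemblyRecord.from_pairs(contigs)


def random_metrics(rng: np.random.Generator) -> QualityMetrics:
    """A random quality-metric vector spanning both sides of every
    threshold, for truth-table testing."""
    category = GenomeCategory(rng.choice(["isolate", "MAG", "SAG"]))
    maybe = lambda v: None if rng.random() < 0.15 else v
    date = None
    if rng.random() < 0.5:
        date = _dt.date(2020, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 2556)))
    return QualityMetrics(
        category=category,
        completeness_pct=maybe(float(np.round(rng.uniform(80, 100), 2))),
        contamination_pct=maybe(float(np.round(rng.uniform(0, 10), 2))),
        coverage_x=maybe(float(np.round(rng.uniform(0, 40), 1))),
        trna_count=maybe(int(rng.integers(0, 21))),
        ssu_completeness_pct=maybe(float(np.round(rng.uniform(40, 100), 1))),
        ssu_chimera_pass=maybe(bool(rng.random() < 0.8)),
        taxonomy_concordant=maybe(bool(rng.random() < 0.8)),
        raw_reads_deposited=bool(rng.random() < 0.8),
        assembly_deposited=bool(rng.random() < 0.9),
        effective_publication_date=date,
    )


def passing_metrics(
    category: GenomeCategory = GenomeCategory.MAG,
    completeness: float = 98.06,
    contamination: float = 0.49,
) -> QualityMetrics:
    """Metrics that satisfy every required and recommended criterion."""
    return QualityMetrics(
        category=category,
        completeness_pct=completeness,
        contamination_pct=contamination,
        coverage_x=30.0,
        trna_count=20,
        ssu_completeness_pct=100.0,
        ssu_chimera_pass=True,
        taxonomy_concordant=True,
        raw_reads_deposited=True,
        assembly_deposited=True,
    )


def type_genome_standin(seed: int = 0) -> AssemblyRecord:
    """Synthetic stand-in with the published dimensions of the worked
    type-genome example: exactly 27 contigs, 1,277,965 bp total and a 52 %
    GC target.

    The real assembly (INSDC accession GCA_021323375.2) is not bundled; this
    generator reproduces its headline statistics so the statistics pipeline
    can be exercised offline.  Contig lengths follow a lognormal size
    spectrum rescaled to the exact total.
    """
    total, n_contigs = 1_277_965, 27
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(0.0, 0.8, size=n_contigs)
    lengths = np.floor(weights / weights.sum() * total).astype(int)
    lengths = np.maximum(lengths, 500)
    lengths[0] += total - int(lengths.sum())  # exact total
    spec = SynthSpec(
        n_contigs=n_contigs,
        length_law="fixed",
        length_params=tuple(int(l) for l in lengths),
        gc_target=52.0,
        seed=seed + 1,
    )
    return generate_assembly(spec)


# -- registry fixtures ---------------------------------------------------

_SYLLABLES = [
    "ba", "co", "de", "fer", "ga", "lu", "mi", "no", "pra", "qui",
    "ru", "sa", "ther", "vo", "xan", "ze",
]


def _random_word(rng: np.random.Generator, n_syllables: int) -> str:
    parts = [str(rng.choice(_SYLLABLES)) for _ in range(n_syllables)]
    return "".join(parts)


def _genus_name(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        word = _random_word(rng, int(rng.integers(3, 6))).capitalize()
        # keep clear of reserved rank suffixes
        if word.lower().endswith(("aceae", "ales", "ia", "ota")):
            continue
        if word.casefold() not in used:
            used.add(word.casefold())
            return word


def _epithet(rng: np.random.Generator) -> str:
    return _random_word(rng, int(rng.integers(3, 6)))


@dataclass
class RegistryAnswerKey:
    """Ground truth emitted alongside a generated registry fixture."""

    homonym_pairs: list[tuple[str, str]] = field(default_factory=list)
    candidatus_raw_names: list[str] = field(default_factory=list)
    priority_order: list[str] = field(default_factory=list)  # entry ids, ascending date
    correct_name_entry_id: Optional[str] = None


def generate_registry_fixture(
    n_entries: int, seed: int
) -> tuple[Registry, RegistryAnswerKey]:
    """Build a populated registry with known structure.

    Produces roughly ``n_entries`` valid entries across ranks (each species
    with its genus as parent context), plus planted material recorded in the
    answer key: one homonym pair (a second proposal that must be rejected),
    a small *Candidatus* intake list, and a set of competing names with a
    known priority ordering.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    key = RegistryAnswerKey()
    registry = Registry()

    base_date = _dt.date(2023, 1, 15)
    qc = qc_report(None, passing_metrics())

    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"fix-{serial:05d}"

    def add_valid(
        name: TaxonName, type_: TypeDesignation, date: _dt.date, path: int = 1
    ) -> RegistryEntry:
        entry = RegistryEntry(
            entry_id=next_id(),
            name=name,
            type=type_,
            status=EntryStatus.VALID,
            path=path,
            created_date=date,
            doi=f"10.99999/fixture.{serial}" if path == 1 else None,
            priority_date=date,
            qc=qc if name.rank in (Rank.SPECIES, Rank.SUBSPECIES) else None,
        )
        registry.entries[entry.entry_id] = entry
        return entry

    genus_entries: list[RegistryEntry] = []
    n_genera = max(1, n_entries // 2)
    # distinct dates so the planted priority ordering is unambiguous
    offsets = rng.choice(700, size=n_genera, replace=False)
    for g in range(n_genera):
        genus_word = _genus_name(rng, used)
        date = base_date + _dt.timedelta(days=int(offsets[g]))
        sp_name = TaxonName(
            rank=Rank.SPECIES, genus_part=genus_word, epithet=_epithet(rng),
            etymology="N.L. n., a synthetic fixture name",
        )
        species = add_valid(
            sp_name,
            TypeDesignation(
                kind=TypeKind.GENOME_ASSEMBLY,
                accession=f"GCA_{rng.integers(10**8, 10**9 - 1)}.1",
                is_ts=True,
            ),
            date,
        )
        genus = add_valid(
            TaxonName(rank=Rank.GENUS, genus_part=genus_word,
                      etymology="N.L. n., a synthetic fixture name"),
            TypeDesignation(kind=TypeKind.SPECIES_REF,
                            ref_entry_id=species.entry_id, is_ts=True),
            date,
        )
        genus_entries.append(genus)
        if len(registry) >= n_entries:
            break

    # a family above the first genus, when there is room
    if len(registry) < n_entries and genus_entries:
        fam_word = genus_entries[0].name.genus_part + "aceae"
        add_valid(
            TaxonName(rank=Rank.FAMILY, genus_part=fam_word),
            TypeDesignation(kind=TypeKind.GENUS_REF,
                            ref_entry_id=genus_entries[0].entry_id),
            base_date,
        )

    registry._check_homonym_invariant()

    # planted homonym: re-proposing the first genus name must be rejected
    first_genus = genus_entries[0].name.genus_part
    key.homonym_pairs.append((genus_entries[0].entry_id, first_genus))

    # planted Candidatus intake set (raw strings, as found in literature)
    for _ in range(3):
        word = _genus_name(rng, used)
        key.candidatus_raw_names.append(f"Candidatus {word} {_epithet(rng)}")

    # planted priority ordering among the genus entries
    by_date = sorted(genus_entries, key=lambda e: (e.priority_date, e.entry_id))
    key.priority_order = [e.entry_id for e in by_date]
    key.correct_name_entry_id = by_date[0].entry_id if by_date else None

    # one external ICNP name that never collides with fixtures
    registry.external_names.append(
        ExternalName(name_key="externus icnpensis",
                     priority_date=_dt.date(2001, 5, 20))
    )
    return registry, key
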