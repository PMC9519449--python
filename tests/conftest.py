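import datetime as dt

import pytest

from seqcode import (
    Rank,
    Registry,
    TypeDesignation,
    TypeKind,
    parse_name,
    qc_report,
    register_draft,
)
from seqcode.synthetic import passing_metrics


@pytest.fixture
def passing_qc():
    return qc_report(None, passing_metrics())


@pytest.fixture
def wolfra_registry(passing_qc):
    """A registry populated with the worked genus/species/family trio."""
    reg = Registry()
    species = register_draft(
        reg,
        parse_name(
            "Wolframiiraptor gerlachensis", Rank.SPECIES,
            etymology=(
                "ger.lach.en'sis N.L. masc. adj. gerlachensis, of Gerlach, "
                "the town where Great Boiling Spring is located in Nevada"
            ),
        ),
        TypeDesignation(
            kind=TypeKind.GENOME_ASSEMBLY, accession="GCA_021323375.2", is_ts=True
        ),
        created_date=dt.date(2022, 6, 1),
        qc=passing_qc,
    )
    genus = register_draft(
        reg,
        parse_name(
            "Wolframiiraptor", Rank.GENUS,
            etymology=(
                "Wolf.ra.mi.i.rap'tor N.L. neut. n. wolframium, tungsten; "
                "L. masc. n. raptor, snatcher or thief"
            ),
        ),
        TypeDesignation(
            kind=TypeKind.SPECIES_REF, ref_entry_id=species.entry_id, is_ts=True
        ),
        created_date=dt.date(2022, 6, 1),
    )
    family = register_draft(
        reg,
        parse_name("Wolframiiraptoraceae", Rank.FAMILY),
        TypeDesignation(kind=TypeKind.GENUS_REF, ref_entry_id=genus.entry_id),
        created_date=dt.date(2022, 6, 1),
    )
    return reg, species, genus, family


def write_fasta_text(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
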