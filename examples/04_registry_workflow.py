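"""Path-1 registration end to end: draft, DOI, priority, protologue.

Registers the worked species and genus, completes validation by recording
the effective publication's DOI (which fixes the priority date), resolves
priority against a later external name, and prints the generated
protologues.
"""

import datetime as dt

from seqcode import (
    ExternalName,
    Rank,
    Registry,
    TypeDesignation,
    TypeKind,
    attach_doi,
    parse_name,
    qc_report,
    register_draft,
    render_protologue,
    resolve_priority,
)
from seqcode.synthetic import passing_metrics

registry = Registry()
qc = qc_report(None, passing_metrics())

species = register_draft(
    registry,
    parse_name(
        "Wolframiiraptor gerlachensis", Rank.SPECIES,
        etymology="ger.lach.en'sis N.L. masc. adj. gerlachensis, of Gerlach",
    ),
    TypeDesignation(kind=TypeKind.GENOME_ASSEMBLY,
                    accession="GCA_021323375.2", is_ts=True),
    created_date=dt.date(2022, 6, 1),
    qc=qc,
)
print(f"registered {species.name.full_name}: {species.status.value}")

species = attach_doi(
    registry, species.entry_id, "10.1038/s41564-022-01214-9", dt.date(2022, 9, 19)
)
print(f"DOI recorded -> {species.status.value}, priority date {species.priority_date}")

genus = register_draft(
    registry,
    parse_name(
        "Wolframiiraptor", Rank.GENUS,
        etymology="N.L. neut. n. wolframium, tungsten; L. masc. n. raptor, snatcher",
    ),
    TypeDesignation(kind=TypeKind.SPECIES_REF,
                    ref_entry_id=species.entry_id, is_ts=True),
    created_date=dt.date(2022, 6, 1),
)
genus = attach_doi(
    registry, genus.entry_id, "10.1038/s41564-022-01214-9", dt.date(2022, 9, 19)
)

# an external (culture-based code) name published later never displaces it
later_icnp = ExternalName("Wolframiiraptor", dt.date(2023, 5, 1))
ordered = resolve_priority([later_icnp, genus])
print("priority order:",
      [f"{r.label} ({r.source}, {r.priority_date})" for r in ordered])

print("\n--- species protologue ---")
print(render_protologue(registry, species.entry_id))
print("\n--- genus protologue ---")
print(render_protologue(registry, genus.entry_id))
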