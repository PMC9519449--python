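"""Nomenclature checks: orthography, rank suffixes, Candidatus intake.

Parses the worked genus/species/family names (all clean) and a few
deliberately malformed ones, printing each finding code.
"""

from seqcode import Rank, check_name, parse_name, strip_candidatus

for raw, rank in [
    ("Wolframiiraptor", Rank.GENUS),
    ("Wolframiiraptor gerlachensis", Rank.SPECIES),
    ("Wolframiiraptoraceae", Rank.FAMILY),
    ("wolframiiraptor", Rank.GENUS),          # capitalization error
    ("Wolfr4miiraptor", Rank.GENUS),          # digit
    ("Wolframiiraptoraceae", Rank.ORDER),     # wrong rank suffix
]:
    name = parse_name(raw, rank)
    findings = check_name(name)
    verdict = "ok" if not findings else "; ".join(
        f"{f.severity.value}:{f.code}" for f in findings
    )
    print(f"{rank.value:<8} {raw:<28} -> {verdict}")

# Path-2 intake drops the provisional designation:
stripped, was_provisional = strip_candidatus("Candidatus Wolframiiraptor")
print(f"\n'Candidatus Wolframiiraptor' -> {stripped!r} (was Candidatus: {was_provisional})")
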