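"""Query the packaged catalogue of 13 receptor missense variants."""

from fshrdyn.variants import count_by, filter_variants, load_variant_table

records = load_variant_table()
print(f"{len(records)} variants")
print("by rescue outcome:", count_by(records, "rescue_class"))
print("by domain:        ", count_by(records, "domain"))

tmd2 = filter_variants(records, lambda r: r.domain == "TMD2")
print("TMD2 variants:", [r.label for r in tmd2])

proline = filter_variants(records, lambda r: r.proline_involved)
rescued_proline = [r.label for r in proline if r.rescue_class == "rescued"]
print(f"proline-involving substitutions: {[r.label for r in proline]} "
      f"(rescued: {rescued_proline or 'almost none'})")
print("-> proline-involving variants respond poorly to pharmacoperone "
      "rescue; the seven rescued variants cluster in TMD2, TMD6 and ECL3.")
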