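"""Synchronise mixed gene identifiers to canonical ids before enrichment.

Shows the four-way partition of an input list: mapped, unmapped,
ambiguous, duplicates — every token is accounted for exactly once.
"""

from oraset import IdMapTable, map_gene_list

table = IdMapTable(species="dm")
table.add("wg", "FBgn0284084")        # symbol
table.add("wingless", "FBgn0284084")  # full name, same gene
table.add("WNT1", "HGNC:12774")       # human ortholog symbol
table.add("dl", "FBgn0000462")        # dorsal
table.add("Dl", "FBgn0000463")        # Delta: case matters in fly symbols

tokens = ["wg", "wingless", "FBgn0284084", "WNT1", "DL", "mystery42", "wg"]
out = map_gene_list(tokens, table)

print(f"input tokens       : {tokens}")
print(f"mapped             : {list(out.mapped)}")
print(f"unmapped           : {list(out.unmapped)}")
print(f"ambiguous          : {out.ambiguous}")
print(f"duplicates removed : {out.duplicates_removed}")
print(f"partition identity : {out.n_input} = {out.n_mapped_tokens} mapped tokens "
      f"+ {len(out.unmapped)} unmapped + {len(out.ambiguous)} ambiguous "
      f"+ {out.duplicates_removed} duplicates -> {out.partition_holds()}")

print("""
'wingless' and the canonical id collapse onto the already-mapped wg
(counted as duplicates), 'DL' matches both dl and Dl case-insensitively so
it is reported ambiguous rather than guessed, and ambiguous candidates are
kept out of the mapped list by default so enrichment is not inflated with
uncertain members.""")
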