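"""Link imaging and genetic pseudo-identifiers.

A participants table arrives with some genetic_id cells still n/a; a secure
external link file supplies the missing pairs.  The merge fills gaps but
refuses to overwrite an existing, different mapping — that pair is reported
as a conflict for a human to resolve.
"""

from bidsgene import build_link_map, merge_external_links, read_participants_table, resolve
from bidsgene.io import write_participants_table

table = read_participants_table(
    "participant_id\tgenetic_id\n"
    "sub-01\tG0001\n"
    "sub-02\tn/a\n"
    "sub-03\tn/a\n")

external_pairs = [("sub-02", "G0002"),   # fills a gap
                  ("sub-01", "G9999"),   # conflicts with G0001 -> reported
                  ("sub-99", "G0042")]   # unknown participant -> reported

merged, conflicts = merge_external_links(table, external_pairs)
print(write_participants_table(merged))
for c in conflicts:
    print(f"conflict: {c.participant_id} -> {c.genetic_id} ({c.reason})")

link = build_link_map(merged)
print(f"linked={link.n_linked} unlinked={link.n_unlinked}")
print("sub-02 resolves to", resolve(link, "sub-02"))
# Two conflicts are reported and sub-01 keeps G0001: external link files can
# add information but never silently change an existing pseudo-ID mapping.
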