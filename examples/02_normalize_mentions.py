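"""Normalize raw mention text: plural folding, positional words,
abbreviation expansion.

Positional modifiers (left, lower, bilaterally...) are split off before
matching and re-attached to the final label; multi-part abbreviations
like HEENT expand to several body parts at once.
"""

from anatomap import (
    Mention,
    Resources,
    load_ontology,
    normalize_mention,
    reattach_positional,
    resolve_term,
)

onto = load_ontology()
resources = Resources.default()

for surface in ("legs bilaterally", "left extremities", "HEENT", "EXT", "the heart"):
    m = Mention("doc1", "m", 0, len(surface), surface)
    nm = normalize_mention(m, resources, onto)
    print(f"{surface!r:20} core={' '.join(nm.core_tokens)!r:10}"
          f" positionals={list(nm.positionals)}"
          f" expansions={['/'.join(e) for e in nm.expansions]}"
          f" via {nm.provenance}")

# re-attachment produces the final label the clinician reads
part = resolve_term(onto, ("leg",))
print("final label:", reattach_positional(["bilateral"], part.formal_name))
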