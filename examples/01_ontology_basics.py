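"""Load the packaged Tree of Human Body Parts and query it.

The tree organises anatomy by position: nine top-level regions, with
organs and tissues as sublayers. Lookup happens on stemmed token
sequences, so surface variation (plurals, synonyms, abbreviations that
are ontology aliases) resolves to the same node.
"""

from anatomap import find_matches_in_text, load_ontology, resolve_term, stem_and_clean
from anatomap.ontology import validate_ontology

onto = load_ontology()
print(f"{len(onto)} nodes, roots: {sorted(r.formal_name for r in onto.roots)}")
print(validate_ontology(onto).render())

for term in ("abd", "arteries", "mitral valve", "myocarditis"):
    part = resolve_term(onto, stem_and_clean(term))
    print(f"{term!r:18} -> {part.formal_name if part else 'not matched'}")

text = "The heart pumps blood to the lungs and the lower extremity."
for occ in find_matches_in_text(onto, stem_and_clean(text)):
    print(f"in text: {occ.part_id:16} offsets={occ.offsets} count={occ.count}")
# counts feed the frequency score; offsets feed the distance score.
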