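"""Score body-part candidates found in an explanation text.

For a term with no ontology match ("electrocardiography"), its
knowledge-base explanation is scanned for body parts; each candidate n
is scored a*f(D(n)) + b*f(F(n)) — a cosine-transformed distance from
the text onset plus its occurrence count, the first-appearing candidate
boosted 2.5x. The argmax is the mapping.
"""

from anatomap import (
    ScoringParams,
    find_matches_in_text,
    load_ontology,
    preprocess_explanation,
    rank_candidates,
)

onto = load_ontology()
text = (
    "Electrocardiography records the electrical activity of the heart "
    "using electrodes placed on the chest. The heart generates small "
    "electrical changes that are detected across the thorax during "
    "each heartbeat."
)
tokens = preprocess_explanation(text)
occs = find_matches_in_text(onto, tokens)

for cand in rank_candidates(occs, onto, ScoringParams()):
    flag = " (first)" if cand.is_first else ""
    print(f"{cand.part_id:8} D={cand.D:5.2f} F={cand.F} "
          f"f_D={cand.f_D:.3f} f_F={cand.f_F:.1f} score={cand.score:6.2f}{flag}")
# the head of the list — heart — is the selected mapping; chest absorbs
# both 'chest' and its alias 'thorax' but appears later and scores lower.
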