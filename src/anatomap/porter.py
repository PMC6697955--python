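"""Porter's suffix-stripping stemmer.

A self-contained implementation of the classic 1980 algorithm, used to
unify inflected surface forms ("arteries"/"artery", "extremities"/
"extremity") on both sides of every dictionary lookup in this package:
ontology aliases, mention text and knowledge-base explanation prose are
all stemmed with the same function before matching.

Only lowercase alphabetic tokens longer than two characters are altered;
anything else (digits, abbreviation-like short tokens) passes through
unchanged, which keeps tokens such as "abd" or "t2" stable.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem_part: str) -> int:
    # number of VC sequences in the collapsed C/V pattern
    pattern: list[str] = []
    for i in range(len(stem_part)):
        tag = "C" if _is_cons(stem_part, i) else "V"
        if not pattern or pattern[-1] != tag:
            pattern.append(tag)
    return "".join(pattern).count("VC")


def _has_vowel(stem_part: str) -> bool:
    return any(not _is_cons(stem_part, i) for i in range(len(stem_part)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _cvc(word: str) -> bool:
    # *o condition: stem ends cvc where the final c is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _step1ab(w: str) -> str:
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        w = _step1b_fixup(w)
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        w = _step1b_fixup(w)
    return w


def _step1b_fixup(w: str) -> str:
    if w.endswith(("at", "bl", "iz")):
        return w + "e"
    if _ends_double_cons(w) and w[-1] not in "lsz":
        return w[:-1]
    if _measure(w) == 1 and _cvc(w):
        return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

# longest-first so e.g. "ement" is tried before "ment" before "ent"
_STEP4 = (
    "ement", "ance", "ence", "able", "ible", "ment", "ant", "ent", "ion",
    "ism", "ate", "iti", "ous", "ive", "ize", "ou", "al", "er", "ic",
)


def _replace_suffixes(w: str, table, min_measure: int) -> str:
    for suffix, repl in table:
        if w.endswith(suffix):
            stem_part = w[: -len(suffix)]
            if _measure(stem_part) > min_measure:
                return stem_part + repl
            return w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem_part = w[: -len(suffix)]
            if _measure(stem_part) > 1:
                if suffix == "ion" and not stem_part.endswith(("s", "t")):
                    return w
                return stem_part
            return w
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _cvc(w[:-1])):
            w = w[:-1]
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


def stem(token: str) -> str:
    """Stem one lowercase token; non-alpha or very short tokens pass through."""
    if len(token) <= 2 or not token.isalpha():
        return token
    w = _step1ab(token)
    w = _step1c(w)
    w = _replace_suffixes(w, _STEP2, 0)
    w = _replace_suffixes(w, _STEP3, 0)
    w = _step4(w)
    w = _step5(w)
    return w
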