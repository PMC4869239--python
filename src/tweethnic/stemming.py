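"""Suffix-stripping stemmer (Porter's algorithm).

Classic five-step Porter stemmer, implemented from the original algorithm
description and applied to convergence (see :func:`porter_stem`).  It maps
inflected/derived forms onto a shared stem so that a document-term matrix
pools them into one column: ``together -> togeth``, ``running -> run``,
``relational -> relat``.  Only lowercase alphabetic tokens are
meaningfully stemmed; anything shorter than three characters is returned
unchanged (Porter's convention).
"""

from __future__ import annotations

__all__ = ["porter_stem"]

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, min_m: int) -> str | None:
    """If *word* ends with *suffix* and the stem measure is > min_m, swap."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_m:
        return stem + repl
    return word  # suffix matched but condition failed: no further rules


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        stem = w[:-3]
        return stem + "ee" if _measure(stem) > 0 else w
    flag = False
    if w.endswith("ed") and _has_vowel(w[:-2]):
        w, flag = w[:-2], True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w, flag = w[:-3], True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_consonant(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _ends_cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _has_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _apply_rules(w: str, rules: list[tuple[str, str]], min_m: int) -> str:
    for suffix, repl in rules:
        out = _replace(w, suffix, repl, min_m)
        if out is not None:
            return out
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) <= 1:
                return w
            if suffix == "ion" and stem and stem[-1] not in "st":
                return w
            return stem
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    if _ends_double_consonant(w) and w[-1] == "l" and _measure(w) > 1:
        w = w[:-1]
    return w


def _stem_once(token: str) -> str:
    if len(token) <= 2:
        return token
    w = _step1a(token)
    w = _step1b(w)
    w = _step1c(w)
    w = _apply_rules(w, _STEP2, 0)
    w = _apply_rules(w, _STEP3, 0)
    w = _step4(w)
    w = _step5(w)
    return w


def porter_stem(token: str) -> str:
    """Stem one lowercase token.

    The five-step pass is applied to convergence so the map is a
    projection: ``stem(stem(t)) == stem(t)`` for every token.  A single
    pass already is a fixed point for almost all English words; the
    iteration only shortens a few residual forms further (e.g. the
    latinate plural ``metastases`` passes through ``metastas`` to
    ``metasta``).
    """
    w = token
    for _ in range(len(token) + 1):
        nxt = _stem_once(w)
        if nxt == w:
            return w
        w = nxt
    return w
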