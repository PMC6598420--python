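"""Porter stemming and a fixed English stop-word list.

The stemmer is a from-scratch implementation of Porter's 1980 suffix
stripping algorithm (steps 1a-5b), the variant used throughout the
information-retrieval literature. The stop-word list is frozen here so
preprocessing is stable across library versions.
"""

from __future__ import annotations

__all__ = ["PorterStemmer", "stem", "STOP_WORDS", "preprocess_tokens"]

#: fixed English stop-word list (function words, pronouns, auxiliaries)
STOP_WORDS = frozenset(
    """a about above after again against all am an and any are aren as at be
    because been before being below between both but by can cannot could
    couldn did didn do does doesn doing don down during each few for from
    further had hadn has hasn have haven having he her here hers herself him
    himself his how i if in into is isn it its itself just me more most
    mustn my myself no nor not now of off on once only or other ought our
    ours ourselves out over own same shan she should shouldn so some such
    than that the their theirs them themselves then there these they this
    those through to too under until up very was wasn we were weren what
    when where which while who whom why will with won would wouldn you your
    yours yourself yourselves t s ll ve re d m""".split()
)

_VOWELS = "aeiou"


class PorterStemmer:
    """Porter (1980) suffix-stripping stemmer."""

    def stem(self, word: str) -> str:
        w = word.lower()
        if len(w) <= 2:
            return w
        w = self._step1a(w)
        w = self._step1b(w)
        w = self._step1c(w)
        w = self._step2(w)
        w = self._step3(w)
        w = self._step4(w)
        w = self._step5a(w)
        w = self._step5b(w)
        return w

    # -- letter classes ----------------------------------------------------

    def _cons(self, w: str, i: int) -> bool:
        ch = w[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self._cons(w, i - 1)
        return True

    def _measure(self, stem: str) -> int:
        """Number of vowel-consonant sequences [C](VC)^m[V]."""
        m = 0
        i = 0
        n = len(stem)
        while i < n and self._cons(stem, i):
            i += 1
        while i < n:
            while i < n and not self._cons(stem, i):
                i += 1
            if i >= n:
                break
            m += 1
            while i < n and self._cons(stem, i):
                i += 1
        return m

    def _has_vowel(self, stem: str) -> bool:
        return any(not self._cons(stem, i) for i in range(len(stem)))

    def _double_cons(self, w: str) -> bool:
        return len(w) >= 2 and w[-1] == w[-2] and self._cons(w, len(w) - 1)

    def _cvc(self, w: str) -> bool:
        if len(w) < 3:
            return False
        return (
            self._cons(w, len(w) - 3)
            and not self._cons(w, len(w) - 2)
            and self._cons(w, len(w) - 1)
            and w[-1] not in "wxy"
        )

    # -- steps -------------------------------------------------------------

    def _step1a(self, w: str) -> str:
        if w.endswith("sses"):
            return w[:-2]
        if w.endswith("ies"):
            return w[:-2]
        if w.endswith("ss"):
            return w
        if w.endswith("s"):
            return w[:-1]
        return w

    def _step1b(self, w: str) -> str:
        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                return w[:-1]
            return w
        flag = False
        if w.endswith("ed") and self._has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and self._has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                return w + "e"
            if self._double_cons(w) and w[-1] not in "lsz":
                return w[:-1]
            if self._measure(w) == 1 and self._cvc(w):
                return w + "e"
        return w

    def _step1c(self, w: str) -> str:
        if w.endswith("y") and self._has_vowel(w[:-1]):
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

    def _map_suffix(self, w: str, table, min_m: int) -> str:
        for suf, rep in table:
            if w.endswith(suf):
                stem = w[: -len(suf)]
                if self._measure(stem) > min_m - 1:
                    return stem + rep
                return w
        return w

    def _step2(self, w: str) -> str:
        return self._map_suffix(w, self._STEP2, min_m=1)

    def _step3(self, w: str) -> str:
        return self._map_suffix(w, self._STEP3, min_m=1)

    _STEP4 = (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    )

    def _step4(self, w: str) -> str:
        for suf in self._STEP4:
            if w.endswith(suf):
                stem = w[: -len(suf)]
                if suf == "ion" and not stem.endswith(("s", "t")):
                    continue
                if self._measure(stem) > 1:
                    return stem
                return w
        return w

    def _step5a(self, w: str) -> str:
        if w.endswith("e"):
            stem = w[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._cvc(stem)):
                return stem
        return w

    def _step5b(self, w: str) -> str:
        if w.endswith("ll") and self._measure(w) > 1:
            return w[:-1]
        return w


_STEMMER = PorterStemmer()


def stem(word: str) -> str:
    """Stem a single lowercase word with the shared stemmer instance."""
    return _STEMMER.stem(word)


def preprocess_tokens(
    tokens, *, stem_tokens: bool = False, remove_stop: bool = False
) -> list[str]:
    """Optionally drop stop words and stem the remaining tokens."""
    out = tokens
    if remove_stop:
        out = [t for t in out if t not in STOP_WORDS]
    if stem_tokens:
        out = [_STEMMER.stem(t) for t in out]
    return list(out)
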