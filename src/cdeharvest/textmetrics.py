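"""String-similarity primitives used for data-element name matching.

Three measures drive the deduplication of raw CRF item labels:

* Levenshtein edit distance — absolute typo budget,
* Jaro-Winkler similarity — order-tolerant similarity with a bonus for a
  shared prefix (label variants usually agree on the head noun),
* original Metaphone — phonetic code, used both for spelling-variant
  agreement (Hemoglobin / Haemoglobin) and as the blocking key of the
  clustering stage.

All three are implemented here rather than imported so that the matching
behaviour is fully pinned down by this module and its tests.
"""

from __future__ import annotations

_VOWELS = frozenset("AEIOU")


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b``."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):  # keep the inner row short
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,  # deletion
                    cur[j - 1] + 1,  # insertion
                    prev[j - 1] + (ca != cb),  # substitution
                )
            )
        prev = cur
    return prev[-1]


def jaro(a: str, b: str) -> float:
    """Jaro similarity in [0, 1].

    Characters match when equal and within ``max(|a|,|b|)//2 - 1``
    positions of each other; transpositions are half the number of
    matched characters that disagree in order.
    """
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    match_a = [False] * la
    match_b = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    sa = [ca for i, ca in enumerate(a) if match_a[i]]
    sb = [cb for j, cb in enumerate(b) if match_b[j]]
    t = sum(x != y for x, y in zip(sa, sb)) / 2.0
    return (m / la + m / lb + (m - t) / m) / 3.0


def jaro_winkler(a: str, b: str, prefix_weight: float = 0.1) -> float:
    """Jaro similarity boosted by a common-prefix term.

    ``sim = jaro + L * p * (1 - jaro)`` where L is the length of the
    common prefix capped at 4 and p the prefix weight (<= 0.25 so the
    result stays within [0, 1]).  Symmetric in its arguments.
    """
    if not 0.0 <= prefix_weight <= 0.25:
        raise ValueError("prefix_weight must lie in [0, 0.25]")
    j = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a[:4], b[:4]):
        if ca != cb:
            break
        prefix += 1
    return j + prefix * prefix_weight * (1.0 - j)


def metaphone(s: str) -> str:
    """Original Metaphone phonetic code of the alphabetic content of ``s``.

    Non-alphabetic characters are ignored (a multi-word label is encoded
    as one run); vowels are coded only in initial position; '0' stands
    for the 'th' sound.  Empty alphabetic content encodes to ''.
    """
    word = "".join(ch for ch in s.upper() if "A" <= ch <= "Z")
    if not word:
        return ""

    # initial-cluster exceptions
    if word[:2] in ("AE", "GN", "KN", "PN", "WR"):
        word = word[1:]
    elif word[:2] == "WH":
        word = "W" + word[2:]
    elif word[0] == "X":
        word = "S" + word[1:]

    out: list[str] = []
    n = len(word)
    i = 0
    while i < n:
        c = word[i]
        if i > 0 and c == word[i - 1] and c != "C":
            i += 1
            continue
        prev = word[i - 1] if i > 0 else ""
        nxt = word[i + 1] if i + 1 < n else ""
        nxt2 = word[i + 2] if i + 2 < n else ""

        if c in _VOWELS:
            if i == 0:
                out.append(c)
        elif c == "B":
            # silent terminal B after M (thumb, lamb)
            if not (i == n - 1 and prev == "M"):
                out.append("B")
        elif c == "C":
            if nxt == "I" and nxt2 == "A":  # -cia-
                out.append("X")
            elif nxt == "H":
                out.append("K" if prev == "S" else "X")  # school vs. chart
            elif nxt in ("I", "E", "Y"):
                out.append("S")
            else:
                out.append("K")
        elif c == "D":
            if nxt == "G" and nxt2 in ("E", "I", "Y"):  # edge, budging
                out.append("J")
                i += 1  # the G is consumed
            else:
                out.append("T")
        elif c == "F":
            out.append("F")
        elif c == "G":
            if nxt == "H":
                # gh is silent unless followed by a vowel (night, weight)
                if nxt2 and nxt2 in _VOWELS:
                    out.append("K")
            elif nxt == "N":
                pass  # sign, gnaw
            elif nxt in ("I", "E", "Y"):
                out.append("J")
            else:
                out.append("K")
        elif c == "H":
            if prev and prev in _VOWELS and (not nxt or nxt not in _VOWELS):
                pass  # ah, oh
            elif prev and prev in "CSPTG":
                pass  # digraph already handled
            else:
                out.append("H")
        elif c == "J":
            out.append("J")
        elif c == "K":
            if prev != "C":
                out.append("K")
        elif c in ("L", "M", "N", "R"):
            out.append(c)
        elif c == "P":
            if nxt == "H":
                out.append("F")
                i += 1
            else:
                out.append("P")
        elif c == "Q":
            out.append("K")
        elif c == "S":
            if nxt == "H":
                out.append("X")
            elif nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            else:
                out.append("S")
        elif c == "T":
            if nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            elif nxt == "H":
                out.append("0")
            elif nxt == "C" and nxt2 == "H":
                pass  # catch -> silent t
            else:
                out.append("T")
        elif c == "V":
            out.append("F")
        elif c == "W":
            if nxt in _VOWELS:
                out.append("W")
        elif c == "X":
            out.append("KS")
        elif c == "Y":
            if nxt in _VOWELS:
                out.append("Y")
        elif c == "Z":
            out.append("S")
        i += 1
    return "".join(out)
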