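"""Independent reference implementations used as test oracles.

These are deliberately written with different algorithms / control flow
than the package's own implementations, so that agreement on large
random samples is meaningful:

* Levenshtein — the ``edlib`` alignment library (external C code).
* Jaro-Winkler — a queue-based matcher built directly from the
  published definition.
* Metaphone — a second transcription of the original transformation
  rules with table-driven control flow.
"""

from __future__ import annotations

from collections import defaultdict, deque

import edlib


def levenshtein_edlib(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def levenshtein_recursive(a: str, b: str) -> int:
    """Exponential-recursion definition (tiny strings only)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        levenshtein_recursive(a[1:], b) + 1,
        levenshtein_recursive(a, b[1:]) + 1,
        levenshtein_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )


def jaro_reference(s1: str, s2: str) -> float:
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(max(len(s1), len(s2)) // 2 - 1, 0)
    avail: dict[str, deque] = defaultdict(deque)
    for j, ch in enumerate(s2):
        avail[ch].append(j)
    matched_i: list[int] = []
    matched_j: list[int] = []
    for i, ch in enumerate(s1):
        q = avail[ch]
        while q and q[0] < i - window:
            q.popleft()
        if q and q[0] <= i + window:
            matched_j.append(q.popleft())
            matched_i.append(i)
    m = len(matched_i)
    if m == 0:
        return 0.0
    s1m = [s1[i] for i in matched_i]
    s2m = [s2[j] for j in sorted(matched_j)]
    transpositions = sum(x != y for x, y in zip(s1m, s2m)) / 2.0
    return (m / len(s1) + m / len(s2) + (m - transpositions) / m) / 3.0


def jaro_winkler_reference(s1: str, s2: str, p: float = 0.1) -> float:
    j = jaro_reference(s1, s2)
    ell = 0
    while ell < min(4, len(s1), len(s2)) and s1[ell] == s2[ell]:
        ell += 1
    return j + ell * p * (1.0 - j)


# --- original Metaphone, second transcription ------------------------------

_VOWELS = "AEIOU"


def _keep_alpha_upper(s: str) -> str:
    return "".join(c for c in s.upper() if c.isalpha() and c.isascii())


def metaphone_reference(s: str) -> str:
    w = _keep_alpha_upper(s)
    if not w:
        return ""
    head2 = w[:2]
    if head2 in {"AE", "GN", "KN", "PN", "WR"}:
        w = w[1:]
    elif head2 == "WH":
        w = "W" + w[2:]
    elif w.startswith("X"):
        w = "S" + w[1:]

    def at(k: int) -> str:
        return w[k] if 0 <= k < len(w) else ""

    code = []
    skip = 0
    for i, c in enumerate(w):
        if skip:
            skip -= 1
            continue
        if i and c == at(i - 1) and c != "C":
            continue
        p, n1, n2 = at(i - 1), at(i + 1), at(i + 2)
        last = i == len(w) - 1
        if c in _VOWELS:
            if i == 0:
                code.append(c)
            continue
        if c == "B":
            if not (last and p == "M"):
                code.append("B")
        elif c == "C":
            if (n1, n2) == ("I", "A"):
                code.append("X")
            elif n1 == "H":
                code.append("K" if p == "S" else "X")
            elif n1 in {"I", "E", "Y"}:
                code.append("S")
            else:
                code.append("K")
        elif c == "D":
            if n1 == "G" and n2 in {"E", "I", "Y"}:
                code.append("J")
                skip = 1
            else:
                code.append("T")
        elif c == "G":
            if n1 == "H":
                if n2 in set(_VOWELS):
                    code.append("K")
            elif n1 == "N":
                pass
            elif n1 in {"I", "E", "Y"}:
                code.append("J")
            else:
                code.append("K")
        elif c == "H":
            after_vowel_no_vowel = p in set(_VOWELS) and n1 not in set(_VOWELS)
            if after_vowel_no_vowel or p in set("CSPTG"):
                pass
            else:
                code.append("H")
        elif c == "K":
            if p != "C":
                code.append("K")
        elif c == "P":
            if n1 == "H":
                code.append("F")
                skip = 1
            else:
                code.append("P")
        elif c == "S":
            if n1 == "H":
                code.append("X")
            elif n1 == "I" and n2 in {"O", "A"}:
                code.append("X")
            else:
                code.append("S")
        elif c == "T":
            if n1 == "I" and n2 in {"O", "A"}:
                code.append("X")
            elif n1 == "H":
                code.append("0")
            elif n1 == "C" and n2 == "H":
                pass
            else:
                code.append("T")
        elif c == "W":
            if n1 in set(_VOWELS):
                code.append("W")
        elif c == "Y":
            if n1 in set(_VOWELS):
                code.append("Y")
        elif c in {"F", "J", "L", "M", "N", "R"}:
            code.append(c)
        elif c == "Q":
            code.append("K")
        elif c == "V":
            code.append("F")
        elif c == "X":
            code.append("KS")
        elif c == "Z":
            code.append("S")
    return "".join(code)


def brute_force_ranking(clusters, assignments, trials, weight="per_trial"):
    """O(n^2)-style independent recomputation of the element ranking.

    Returns a list of (cde_id_with_optional_domain_suffix, domain,
    weighted_score, n_trials, n_form_occurrences) tuples in rank order,
    built with plain loops and an explicit sort.
    """
    enrollment = {t.trial_id: t.planned_enrollment for t in trials}
    dom_of_form = {a.form_id: a.domain_key for a in assignments}
    entries = []
    for c in clusters:
        domains = sorted({dom_of_form.get(fid, "unassigned")
                          for _tr, fid, _iid in c.members})
        for dk in domains:
            occ = [(tr, fid) for tr, fid, _iid in c.members
                   if dom_of_form.get(fid, "unassigned") == dk]
            trial_ids = sorted({tr for tr, _ in occ})
            form_ids = sorted({fid for _, fid in occ})
            if weight == "per_trial":
                score = 0
                for t in trial_ids:
                    score += enrollment[t]
            else:
                score = 0
                for t in trial_ids:
                    forms_t = {fid for tr, fid in occ if tr == t}
                    score += enrollment[t] * len(forms_t)
            cde_id = c.cluster_id if len(domains) == 1 else f"{c.cluster_id}@{dk}"
            entries.append((cde_id, c.canonical_label, dk, score,
                            len(trial_ids), len(form_ids)))
    entries.sort(key=lambda e: (-e[3], -e[4], e[1].casefold(), e[0]))
    return entries
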