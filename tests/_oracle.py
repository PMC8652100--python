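"""Naive, independent re-implementations of the row-level filters.

Plain-Python row scans used only as oracles: given a list of row dicts they
return the set of kept row indices.  Deliberately share no code with the
package implementation.
"""

import math


def keep_info(rows, threshold=0.9):
    kept = set()
    for i, r in enumerate(rows):
        v = r.get("INFO")
        if v is None:
            kept.add(i)
            continue
        v = float(v)
        if 0 <= v <= 1 and not v < threshold:
            kept.add(i)
    return kept


def keep_n_outliers(rows, k=5.0):
    ns = []
    for r in rows:
        v = float(r["N"])
        # round half away from zero
        ns.append(math.floor(abs(v) + 0.5) * (1 if v >= 0 else -1))
    mean = sum(ns) / len(ns)
    if len(ns) > 1:
        sd = math.sqrt(sum((x - mean) ** 2 for x in ns) / (len(ns) - 1))
    else:
        sd = 0.0
    bound = mean + k * sd
    return {i for i, n in enumerate(ns) if n > 0 and not n > bound}


def keep_strand_unambiguous(rows):
    kept = set()
    for i, r in enumerate(rows):
        pair = frozenset((str(r["A1"]).upper(), str(r["A2"]).upper()))
        if pair not in (frozenset("AT"), frozenset("CG")):
            kept.add(i)
    return kept


def keep_autosomal(rows):
    return {i for i, r in enumerate(rows) if str(r["CHR"]) not in ("X", "Y", "MT")}


def keep_effect_nonzero(rows):
    kept = set()
    for i, r in enumerate(rows):
        bad = False
        for col in ("Z", "BETA", "LOG_ODDS", "SIGNED_SUMSTAT", "OR"):
            if col in r and r[col] is not None and float(r[col]) == 0.0:
                bad = True
        if not bad:
            kept.add(i)
    return kept


def keep_se_positive(rows):
    return {i for i, r in enumerate(rows) if float(r["SE"]) > 0}


def keep_first_by_key(rows, keyfunc):
    seen, kept = set(), set()
    for i, r in enumerate(rows):
        k = keyfunc(r)
        if k not in seen:
            seen.add(k)
            kept.add(i)
    return kept
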