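"""Independent straight-line oracles used to cross-check the implementation.

The flag oracle re-states the flagging rules as a flat sequence of literal
conditions, written without reference to the package's own code paths.
"""

from itertools import product

from tumoronly.flags import VariantCall

_POPS = ("kg", "danish", "exac", "exac_eur")


def oracle_flags(qual, depth, counts, pop_afs, impacts):
    """Literal re-statement of the per-position flag rules."""
    flags = set()
    if qual < 20:
        flags.add("LQ")
    if depth < 10:
        flags.add("LD")
    if depth == 0:
        flags.add("LF")
        return frozenset(flags)
    aafs = [c / depth for c in counts]

    hf = False
    for f, c in zip(aafs, counts):
        if f > 0.95 and c >= 5:
            hf = True
    non_alt = depth - sum(counts)
    if non_alt < 5:
        for f, c in zip(aafs, counts):
            if f >= 0.05 and c >= 5:
                hf = True
    if hf:
        flags.add("HF")

    qualifying = [
        i for i, (f, c) in enumerate(zip(aafs, counts)) if f >= 0.05 and c >= 5
    ]
    if not qualifying:
        flags.add("LF")
        return frozenset(flags)

    for pop, flag in (("kg", "G5"), ("danish", "DK"), ("exac", "EG"),
                      ("exac_eur", "EE")):
        if all(pop_afs[i].get(pop, 0.0) >= 0.05 for i in qualifying):
            flags.add(flag)
    if all(
        any(pop_afs[i].get(p, 0.0) >= 0.05 for p in _POPS) for i in qualifying
    ):
        flags.add("CO")

    levels = {"modifier": 0, "low": 1, "moderate": 2, "high": 3}
    worst = max(levels[impacts[i]] for i in qualifying)
    flags.add(("I0", "I1", "I2", "I3")[worst])
    return frozenset(flags)


_DB_PATTERNS = [
    {},
    {"kg": 0.30},
    {"danish": 0.50},
    {"exac": 0.06},
    {"exac_eur": 0.052},
    {"kg": 0.30, "danish": 0.50, "exac": 0.06, "exac_eur": 0.052},
    {"kg": 0.04},  # observed but below the 5% commonness threshold
]


def call_grid():
    """~2,000 constructed calls covering every flag boundary.

    Single-alt calls sweep QUAL {10, 19.9, 20, 30} x depth {5, 9, 10, 50,
    100} x support counts straddling the 5%-AAF/5-read/95%-AAF boundaries x
    database patterns x impact {modifier, high}; two-alt calls add the
    CO-without-G5 configuration and joint qualification cases.
    """
    calls = []
    quals = [10.0, 19.9, 20.0, 30.0]
    depths = [5, 9, 10, 50, 100]
    for qual, depth in product(quals, depths):
        base = {0, 1, 4, 5, depth // 2, depth - 5, depth - 4, depth - 1, depth}
        five_pct = int(0.05 * depth)
        base |= {five_pct, five_pct + 1}
        counts = sorted(c for c in base if 0 <= c <= depth)
        for count, pops, impact in product(counts, _DB_PATTERNS,
                                           ("modifier", "high")):
            calls.append(
                VariantCall(
                    sample_id="S", chrom="1", pos=100, ref="A", alts=("T",),
                    qual=qual, hq_depth=depth, hq_alt_counts=(count,),
                    pop_afs=(pops,), impacts=(impact,),
                )
            )
    two_alt_patterns = [
        ({"kg": 0.30}, {"exac": 0.10}),  # CO without any single-source flag
        ({"kg": 0.30}, {"kg": 0.20}),
        ({"kg": 0.30, "danish": 0.5, "exac": 0.1, "exac_eur": 0.1}, {}),
        ({}, {}),
    ]
    for (c1, c2), (p1, p2), (i1, i2) in product(
        [(30, 10), (5, 5), (50, 45), (3, 10), (4, 4)],
        two_alt_patterns,
        [("modifier", "high"), ("moderate", "low")],
    ):
        calls.append(
            VariantCall(
                sample_id="S", chrom="1", pos=200, ref="A", alts=("T", "G"),
                qual=30.0, hq_depth=100, hq_alt_counts=(c1, c2),
                pop_afs=(p1, p2), impacts=(i1, i2),
            )
        )
    return calls
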