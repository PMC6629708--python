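"""Independent brute-force re-statement of the diagnostic-character rule.

Written as a literal clause-by-clause check over every column, sharing no
code with synapodiag.charscan, so the two implementations can be compared
on random alignments.
"""

NUCS = ("A", "C", "G", "T")


def brute_force_scan(loci, taxa, focal, outgroups, threshold, forbid, max_missing):
    """loci: list of (locus_key, rows) with rows a list of strings in *taxa*
    order.  Returns a list of dicts sorted by the ranking rule (no coverage:
    missing count, then locus order, then position)."""
    focal_idx = [taxa.index(t) for t in sorted(focal)]
    out_idx = [taxa.index(t) for t in sorted(outgroups)]
    hits = []
    for locus_order, (key, rows) in enumerate(loci):
        length = len(rows[0])
        for pos in range(length):
            fstates = [rows[i][pos] for i in focal_idx]
            ostates = [rows[i][pos] for i in out_idx]
            fobs = [s for s in fstates if s in NUCS]
            oobs = [s for s in ostates if s in NUCS]
            if not fobs or not oobs:
                continue  # uninformative
            if any(s != fobs[0] for s in fobs):
                continue  # clause (i): focal clade must be invariant
            d = fobs[0]
            missing = len(fstates) - len(fobs)
            if missing > max_missing:
                continue
            best_state, best_count = None, 0
            for s in set(oobs):
                c = oobs.count(s)
                if c > best_count:
                    best_state, best_count = s, c
            if best_count / len(oobs) >= threshold:
                a = best_state
                if a == d:
                    continue  # clause (iii)
                if forbid and d in oobs:
                    continue  # clause (iv)
                hits.append(
                    dict(locus=key, position=pos + 1, kind="derived",
                         ancestral=a, derived=d, missing=missing,
                         order=locus_order)
                )
            else:
                # no qualifying majority: state-only character if the focal
                # state never occurs in the outgroup
                if d not in oobs:
                    hits.append(
                        dict(locus=key, position=pos + 1, kind="state_only",
                             ancestral=None, derived=d, missing=missing,
                             order=locus_order)
                    )
    hits.sort(key=lambda h: (h["missing"], h["order"], h["position"]))
    return hits
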