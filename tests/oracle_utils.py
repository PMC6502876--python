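"""Independent brute-force oracle for the in-silico PCR engine.

Expands both degenerate primers into every concrete variant and substring-
scans — no shared code with the engine's per-position IUPAC matching.
Exact matching only (the setting under which sites are planted).
"""

from pnaprimers.registry import PrimerPair, expand_degenerate, reverse_complement_iupac


def oracle_amplicons(pair: PrimerPair, seq: str, min_product=50, max_product=2000):
    fwd_variants = expand_degenerate(pair.forward.sequence)
    rev_variants = {reverse_complement_iupac(v) for v in expand_degenerate(pair.reverse.sequence)}
    flen = len(pair.forward.sequence)
    rlen = len(pair.reverse.sequence)
    fwd_hits = [i for i in range(len(seq) - flen + 1) if seq[i:i + flen] in fwd_variants]
    rev_hits = [i for i in range(len(seq) - rlen + 1) if seq[i:i + rlen] in rev_variants]
    out = []
    for f in fwd_hits:
        for r in rev_hits:
            length = r + rlen - f
            if r >= f + flen and min_product <= length <= max_product:
                out.append((f, r + rlen, length))
    return sorted(out)
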