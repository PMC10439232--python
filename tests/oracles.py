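"""Independent oracles used by the tests.

Each oracle recomputes an expected result with deliberately naive string
arithmetic (brute-force scans, permutation enumeration, direct slicing) so
it shares no code path with the implementation it checks.
"""

from itertools import permutations, product

from yalicraft.model import IUPAC, canonical_key, revcomp


def naive_find_sites(seq, pattern, circular):
    """O(n*m) both-strand scan for an IUPAC pattern."""

    def matches(s, p):
        return len(s) == len(p) and all(b in IUPAC[c] for b, c in zip(s, p))

    n, m = len(seq), len(pattern)
    if m > n:
        return []
    hits = set()
    src = seq + seq[: m - 1] if circular else seq
    limit = n if circular else n - m + 1
    rc = revcomp(pattern)
    for i in range(limit):
        window = src[i:i + m]
        if matches(window, pattern):
            hits.add((i, "+"))
        if matches(window, rc):
            hits.add((i, "-"))
    return sorted(hits)


def brute_force_circles(fragments, max_len=5):
    """Canonical sequences of every circle formable from <= max_len
    fragments, by explicit enumeration of permutations and orientations."""

    def flip(f):
        return (revcomp(f[0]), revcomp(f[2]), revcomp(f[1]))

    assert len(fragments) <= max_len
    results = set()
    n = len(fragments)
    for r in range(1, n + 1):
        for idxs in permutations(range(n), r):
            for orient in product((0, 1), repeat=r):
                chain = [fragments[i] if o == 0 else flip(fragments[i])
                         for i, o in zip(idxs, orient)]
                ok = all(chain[k][2] and chain[k][2] ==
                         chain[(k + 1) % r][1] for k in range(r))
                if not ok:
                    continue
                seq = "".join(f[0][:len(f[0]) - len(f[2])] for f in chain)
                if seq:
                    results.add(canonical_key(seq))
    return results


def entry_part_slice(vector_seq, recognition="GGTCTC", spacer=1, ov=4):
    """The part released by an entry vector, by direct string slicing.

    Finds the forward and reverse recognition copies, computes the two cut
    windows by hand, and returns the span between them (window bases
    included on both ends).
    """
    doubled = vector_seq + vector_seq
    p = vector_seq.find(recognition)
    q = vector_seq.find(revcomp(recognition))
    assert p >= 0 and q >= 0
    a1 = p + len(recognition) + spacer          # forward cut window start
    a2 = q - spacer - ov                        # reverse cut window start
    if a2 + ov < a1:
        a2 += len(vector_seq)
    return doubled[a1:a2 + ov]


def acceptor_backbone_slice(vector_seq, recognition="GGTCTC", spacer=1, ov=4):
    """The acceptor backbone retained after dropout release: the complement
    span of :func:`entry_part_slice` (cut windows included on both ends)."""
    n = len(vector_seq)
    doubled = vector_seq + vector_seq
    p = vector_seq.find(recognition)
    q = vector_seq.find(revcomp(recognition))
    # acceptor slots put the reverse copy first (left window) and the
    # forward copy second (right window)
    left_window = q - spacer - ov
    right_window = p + len(recognition) + spacer
    if left_window < 0:
        left_window += n
    start = right_window
    end = left_window + ov
    if end < start:
        end += n
    return doubled[start:end]


def lvl1_concatenation_oracle(empty_seq, prom_seq, gene_seq, term_seq,
                              recognition="GGTCTC", spacer=1, ov=4):
    """Expected Lvl1 product by direct concatenation of string slices.

    Joins acceptor backbone + promoter + gene + terminator parts, dropping
    the duplicated 4-nt window at every junction (including the closing
    one), and returns the canonical circular sequence.
    """
    pieces = [acceptor_backbone_slice(empty_seq, recognition, spacer, ov)]
    for part_vec in (prom_seq, gene_seq, term_seq):
        pieces.append(entry_part_slice(part_vec, recognition, spacer, ov))
    seq = "".join(p[:-ov] for p in pieces)
    return canonical_key(seq)


def aari_sections(vector_seq, recognition="CACCTGC", spacer=4, ov=4):
    """(backbone_with_arms, central) sections of an exchange vector, by
    direct slicing at the two hand-computed AarI cut windows.

    The backbone keeps both recognition copies (they point inward); the
    central section is the site-free span between the windows.  Both
    sections include the window bases at both of their ends.
    """
    n = len(vector_seq)
    doubled = vector_seq + vector_seq
    p = vector_seq.find(recognition)
    q = vector_seq.find(revcomp(recognition))
    w_left = p + len(recognition) + spacer      # window after forward copy
    w_right = q - spacer - ov                   # window before reverse copy
    if w_right < 0:
        w_right += n
    central_end = w_right + ov
    if central_end < w_left:
        central_end += n
    central = doubled[w_left:central_end]
    backbone_end = w_left + ov
    start = w_right
    if backbone_end < start:
        backbone_end += n
    backbone = doubled[start:backbone_end]
    return backbone, central


def naive_protospacers(seq):
    """Brute-force NGG protospacer scan of a linear sequence."""
    out = []
    n = len(seq)
    for i in range(n - 2):
        if seq[i + 1:i + 3] == "GG" and i >= 20:
            out.append((seq[i - 20:i], "+", i - 20))
        if seq[i:i + 2] == "CC" and i + 23 <= n:
            out.append((revcomp(seq[i + 3:i + 23]), "-", i + 3))
    return out
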