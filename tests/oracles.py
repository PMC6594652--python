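"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (quadratic DP, exhaustive scans,
full enumeration) and written without reference to the package internals,
so it can serve as a second route for the same quantities.
"""

from itertools import product

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def sw_score(a, b, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Plain-python affine-gap local alignment best score.

    Gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
    return best


def _iupac_matchers():
    sets = {"W": "AT", "R": "AG", "Y": "CT"}
    wrcy = {
        "".join(t)
        for t in product("ACGT", repeat=4)
        if t[0] in sets["W"] and t[1] in sets["R"] and t[2] == "C" and t[3] in sets["Y"]
    }
    rgyw = {
        "".join(t)
        for t in product("ACGT", repeat=4)
        if t[0] in sets["R"] and t[1] == "G" and t[2] in sets["Y"] and t[3] in sets["W"]
    }
    return wrcy, rgyw


WRCY_SET, RGYW_SET = _iupac_matchers()


def aid_hits(seq):
    """(start, class) tuples from exhaustive 4-mer membership tests."""
    out = []
    for i in range(len(seq) - 3):
        kmer = seq[i : i + 4]
        if kmer in WRCY_SET:
            out.append((i, "AID_WRCY"))
        if kmer in RGYW_SET:
            out.append((i, "AID_RGYW"))
    return sorted(out)


def apobec_hits(seq):
    out = []
    for i in range(len(seq) - 1):
        if seq[i : i + 2] == "TC":
            out.append((i, "APOBEC3_TC"))
        if seq[i : i + 2] == "GA":
            out.append((i, "APOBEC3_GA"))
    return sorted(out)


def g4_scores(seq):
    """Per-base run scores by explicit run enumeration."""
    scores = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = j - i
        val = 0
        if seq[i] == "G":
            val = min(run, 4)
        elif seq[i] == "C":
            val = -min(run, 4)
        scores.extend([val] * run)
        i = j
    return scores


def repeat_windows(seq_a, seq_b, window=20, min_identity=0.90):
    """Every qualifying (i, j) window pair, brute force O(n*m*w)."""
    import math

    need = math.ceil(min_identity * window)
    hits = []
    for i in range(len(seq_a) - window + 1):
        wa = seq_a[i : i + window]
        for j in range(len(seq_b) - window + 1):
            wb = seq_b[j : j + window]
            n_match = sum(x == y and x != "N" for x, y in zip(wa, wb))
            if n_match >= need:
                hits.append((i, j))
    return hits


def nearest_distance(pos, intervals):
    best = None
    for s, e in intervals:
        if s <= pos <= e:
            return 0
        d = s - pos if pos < s else pos - e
        best = d if best is None or d < best else best
    return best


def expected_distance_enumeration(intervals, lo, hi):
    vals = [nearest_distance(p, intervals) for p in range(lo, hi + 1)]
    return sum(vals) / len(vals), vals


def resolve_junction_oracle(read, donor, acceptor, diag_d, diag_a):
    """Canonical joint by prefix/suffix perfect-run enumeration.

    ``diag_d``/``diag_a`` are ref-minus-read offsets of the true donor and
    acceptor diagonals (known for simulator-built reads). Independent of
    the package's anchored-extension implementation.
    """
    n = len(read)
    d_end = 0
    while d_end < n and 0 <= d_end + diag_d < len(donor) and read[d_end] == donor[d_end + diag_d]:
        d_end += 1
    a_start = n
    while (
        a_start > 0
        and 0 <= a_start - 1 + diag_a < len(acceptor)
        and read[a_start - 1] == acceptor[a_start - 1 + diag_a]
    ):
        a_start -= 1
    if d_end < a_start:
        ins = read[d_end:a_start]
        return {
            "structure": "insertion" if ins else "blunt",
            "mh_len": 0,
            "insertion_seq": ins,
            "donor_break": d_end + diag_d,
            "acceptor_break": a_start + diag_a,
        }
    if d_end == a_start:
        return {
            "structure": "blunt",
            "mh_len": 0,
            "insertion_seq": "",
            "donor_break": d_end + diag_d,
            "acceptor_break": a_start + diag_a,
        }
    return {
        "structure": "microhomology",
        "mh_len": d_end - a_start,
        "insertion_seq": "",
        "donor_break": d_end + diag_d,
        "acceptor_break": a_start + diag_a,
    }


def pearson_chi2(table):
    """Textbook Pearson chi-square on a 2-row table."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[r][c] for r in range(rows)) for c in range(cols)]
    chi2 = 0.0
    for r in range(rows):
        for c in range(cols):
            exp = row_sums[r] * col_sums[c] / total
            chi2 += (table[r][c] - exp) ** 2 / exp
    return chi2, (rows - 1) * (cols - 1)


def mannwhitney_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (tiny n)."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n = len(x)

    def ustat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1
                elif a == b:
                    u += 0.5
        return u

    u_obs = ustat(tuple(range(n)))
    mu = n * (len(pooled) - n) / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if abs(ustat(idx) - mu) >= dev - 1e-12:
            count += 1
    return count / total
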