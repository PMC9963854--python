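"""Independent brute-force reference implementations used only by tests.

These re-derive pileup tallies and variant calls straight from SAM text by
hand-walking CIGAR strings, deliberately sharing no code with the package's
pysam-based pileup, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import re

import numpy as np
import pysam

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
SKIP_FLAGS = 0x4 | 0x100 | 0x800  # unmapped, secondary, supplementary


def parse_sam_text(path):
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            reads.append(
                {
                    "qname": f[0],
                    "flag": int(f[1]),
                    "rname": f[2],
                    "pos": int(f[3]),
                    "cigar": f[5],
                    "seq": f[9],
                    "qual": f[10],
                }
            )
    return reads


def brute_pileup(path, chrom, start0, end0):
    """Per-position base/quality tallies from direct CIGAR walking.

    Returns (counts, quals): maps 0-based position -> base -> count / list.
    """
    counts: dict[int, dict[str, int]] = {}
    quals: dict[int, dict[str, list]] = {}
    for r in parse_sam_text(path):
        if r["flag"] & SKIP_FLAGS or r["rname"] != chrom or r["cigar"] == "*":
            continue
        rpos = r["pos"] - 1
        qpos = 0
        for n_str, op in CIGAR_RE.findall(r["cigar"]):
            n = int(n_str)
            if op in "M=X":
                for k in range(n):
                    p = rpos + k
                    if start0 <= p < end0:
                        base = r["seq"][qpos + k].upper()
                        q = 0 if r["qual"] == "*" else ord(r["qual"][qpos + k]) - 33
                        counts.setdefault(p, {})
                        counts[p][base] = counts[p].get(base, 0) + 1
                        quals.setdefault(p, {}).setdefault(base, []).append(q)
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
            # H and P consume neither query nor reference
    return counts, quals


def brute_calls(counts, quals, ref_seq, min_avg_qual=20.0, min_var_freq=0.01, min_reads2=10):
    """VarScan-style calls recomputed from brute tallies.

    Returns tuples (pos_1based, ref, alt, depth, alt_reads, vf_percent, mean_qual).
    """
    out = []
    for p in sorted(counts):
        depth = sum(counts[p].values())
        if depth == 0:
            continue
        ref = ref_seq[p].upper()
        best, best_count = None, 0
        for base in "ACGT":
            if base == ref:
                continue
            c = counts[p].get(base, 0)
            if c > best_count:
                best, best_count = base, c
        if best is None or best_count < min_reads2:
            continue
        if best_count / depth < min_var_freq:
            continue
        mean_q = float(np.mean(quals[p][best]))
        if mean_q < min_avg_qual:
            continue
        out.append((p + 1, ref, best, depth, best_count, 100.0 * best_count / depth, mean_q))
    return out


def make_sam(path, ref_name, ref_len, reads):
    """Write a SAM from (start0, seq, quals, flag, cigar) tuples via pysam."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (start, seq, quals, flag, cigar) in enumerate(reads):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"r{i:04d}"
            seg.flag = flag
            seg.reference_name = ref_name
            seg.reference_start = start
            seg.mapping_quality = 60
            seg.cigarstring = cigar
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            out.write(seg)


def random_sam(path, rng, n_reads=60, ref_len=300, n_hot_sites=3):
    """A random SAM with mixed CIGAR shapes, mismatches and skippable reads.

    ``n_hot_sites`` positions get a fixed alternate base substituted in half
    the reads covering them, so some columns clear the caller thresholds.
    Returns the reference sequence.
    """
    bases = np.array(list("ACGT"))
    ref = "".join(rng.choice(bases, ref_len))
    hot = rng.choice(ref_len - 20, size=n_hot_sites, replace=False) + 10
    hot_alt = {int(p): "ACGT"[(("ACGT".index(ref[p])) + 1) % 4] for p in hot}

    reads = []
    for _ in range(n_reads):
        m1 = int(rng.integers(20, 50))
        start = int(rng.integers(0, ref_len - 110))
        shape = rng.random()
        if shape < 0.5:
            ops = [(m1 + 30, "M")]
        elif shape < 0.7:
            ops = [(m1, "M"), (int(rng.integers(1, 4)), "D"), (25, "M")]
        elif shape < 0.9:
            ops = [(m1, "M"), (int(rng.integers(1, 4)), "I"), (25, "M")]
        else:
            ops = [(int(rng.integers(2, 8)), "S"), (m1 + 20, "M")]

        seq_parts = []
        rpos = start
        for n, op in ops:
            if op == "M":
                chunk = list(ref[rpos : rpos + n])
                for k in range(n):
                    p = rpos + k
                    if p in hot_alt and rng.random() < 0.5:
                        chunk[k] = hot_alt[p]
                    elif rng.random() < 0.03:
                        chunk[k] = str(rng.choice(bases))
                seq_parts.append("".join(chunk))
                rpos += n
            elif op in "IS":
                seq_parts.append("".join(rng.choice(bases, n)))
            elif op == "D":
                rpos += n
        seq = "".join(seq_parts)
        quals = rng.integers(10, 41, size=len(seq)).tolist()
        flag = 0
        r = rng.random()
        if r < 0.05:
            flag = 0x100  # secondary: must be ignored by both routes
        elif r < 0.08:
            flag = 0x800  # supplementary
        cigar = "".join(f"{n}{op}" for n, op in ops)
        reads.append((start, seq, quals, flag, cigar))
    make_sam(path, "ref", ref_len, reads)
    return ref
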