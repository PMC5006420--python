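"""Construction helpers for repeat-scan tests: contigs with plain planted
repeat pairs (no RT context), built independently of the package generator."""

from __future__ import annotations

import numpy as np

from oracles import rc


def plant_plain_repeats(contig_length: int, n_repeats: int, seed: int,
                        rep_len_range=(250, 400), sub_rate_range=(0.05, 0.12),
                        margin: int = 8):
    """Random contig with substitution-diverged repeat pairs planted at
    non-overlapping positions; ends of each copy kept invariant so the
    planted extent is sharply defined.

    Returns (sequence, truth list of (a_iv, b_iv, orientation)).
    """
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), contig_length)))
    placed: list[tuple[int, int]] = []
    truth = []

    def _free(start, length):
        return all(start + length + 250 <= s or e + 250 <= start for s, e in placed) \
            and 0 <= start and start + length <= contig_length

    for _ in range(n_repeats):
        rep_len = int(rng.integers(*rep_len_range))
        for _attempt in range(200):
            a = int(rng.integers(0, contig_length - rep_len))
            b = int(rng.integers(0, contig_length - rep_len))
            if abs(a - b) < rep_len + 250:
                continue
            if _free(a, rep_len) and _free(b, rep_len):
                break
        else:
            break
        a, b = sorted((a, b))
        copy = "".join(rng.choice(list("ACGT"), rep_len))
        n_subs = max(1, int(rng.uniform(*sub_rate_range) * rep_len))
        positions = rng.choice(np.arange(margin, rep_len - margin), size=n_subs,
                               replace=False)
        other = list(copy)
        for p in positions:
            other[p] = rng.choice([c for c in "ACGT" if c != copy[p]])
        other = "".join(other)
        orientation = "direct" if rng.random() < 0.7 else "inverted"
        b_seq = other if orientation == "direct" else rc(other)
        seq[a:a + rep_len] = copy
        seq[b:b + rep_len] = b_seq
        placed.extend([(a, a + rep_len), (b, b + rep_len)])
        truth.append(((a, a + rep_len), (b, b + rep_len), orientation))
    return "".join(seq), truth
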