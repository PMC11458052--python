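"""Same/different trial schedules.

The experiment crosses 3 stimulus types (natural, inverted, negated) with 7
orientation-filter levels (0..150 deg in 30-deg steps plus full spectrum),
giving 21 condition cells of 60 trials each: 90 blocks of 14 trials (one
stimulus type per block; 2 trials per filter level), blocks grouped in
consecutive triplets containing each stimulus type once in random order.
The same 30 same-identity and 30 different-identity image pairs are
replicated across all 21 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

STIMULUS_TYPES = ("natural", "inverted", "negated")
FILTER_LEVELS = ("0", "30", "60", "90", "120", "150", "fullspectrum")
TRIALS_PER_FILTER_PER_BLOCK = 2
BLOCKS_PER_TYPE = 30


@dataclass(frozen=True)
class Pair:
    """One probe/target image pair; images are (identity, image_index) ids."""

    probe: tuple[int, int]
    target: tuple[int, int]
    is_same: bool

    def __post_init__(self) -> None:
        if self.is_same:
            if self.probe[0] != self.target[0] or self.probe == self.target:
                raise ValueError("same pair must be two different images of one identity")
        elif self.probe[0] == self.target[0]:
            raise ValueError("different pair must cross identities")


def build_pairs(
    n_identities: int = 10,
    images_per_identity: int = 3,
    seed: int = 0,
    *,
    n_same: int = 30,
    n_diff: int = 30,
) -> list[Pair]:
    """Build the per-participant pair pool (30 same + 30 different by default).

    Same pairs are all within-identity image combinations (10 identities x 3
    images gives exactly the 30 needed).  Different pairs are a random
    2-regular matching: every image appears exactly twice across the
    different pairs, always facing another identity.
    """
    if n_identities < 2 or images_per_identity < 2:
        raise ValueError("need >= 2 identities and >= 2 images per identity")
    rng = np.random.default_rng(seed)

    same_candidates = [
        Pair((i, a), (i, b), True)
        for i in range(n_identities)
        for a, b in combinations(range(images_per_identity), 2)
    ]
    if len(same_candidates) < n_same:
        raise ValueError("not enough within-identity image pairs")
    same = [same_candidates[k] for k in rng.choice(len(same_candidates), n_same, replace=False)]

    images = [(i, j) for i in range(n_identities) for j in range(images_per_identity)]
    if 2 * n_diff % len(images) == 0:
        per_image = 2 * n_diff // len(images)
        slots = [im for im in images for _ in range(per_image)]
    else:
        slots = list(rng.choice(len(images), 2 * n_diff))
        slots = [images[k] for k in slots]
    # random matching; resample until no slot faces its own identity
    for _ in range(1000):
        order = rng.permutation(len(slots))
        probes = [slots[k] for k in order[: n_diff]]
        targets = [slots[k] for k in order[n_diff :]]
        if all(p[0] != t[0] for p, t in zip(probes, targets)):
            break
    else:  # pragma: no cover - astronomically unlikely with defaults
        raise RuntimeError("could not build a cross-identity matching")
    diff = [Pair(p, t, False) for p, t in zip(probes, targets)]
    return same + diff


def build_schedule(pairs: list[Pair], seed: int = 0, subject_id: str = "s01") -> pd.DataFrame:
    """Lay the pair pool out over the full 90-block schedule.

    Returns one row per trial with columns block, trial, stimulus_type,
    filter, pair_id, is_same, probe/target identity and image ids.  Within a
    stimulus type, each condition cell receives every pair exactly once, in a
    fresh random order, dealt two per block.
    """
    rng = np.random.default_rng(seed)
    n_pairs = len(pairs)
    if n_pairs != BLOCKS_PER_TYPE * TRIALS_PER_FILTER_PER_BLOCK:
        raise ValueError(f"expected {BLOCKS_PER_TYPE * TRIALS_PER_FILTER_PER_BLOCK} pairs")

    # per stimulus type x filter: a shuffled deal of all pairs, 2 per block
    deal = {
        (st, f): rng.permutation(n_pairs)
        for st in STIMULUS_TYPES
        for f in FILTER_LEVELS
    }

    rows = []
    block_index = 0
    for triplet in range(BLOCKS_PER_TYPE):
        order = list(rng.permutation(len(STIMULUS_TYPES)))
        for st_idx in order:
            st = STIMULUS_TYPES[st_idx]
            block_trials = []
            for f in FILTER_LEVELS:
                ids = deal[(st, f)][
                    triplet * TRIALS_PER_FILTER_PER_BLOCK : (triplet + 1) * TRIALS_PER_FILTER_PER_BLOCK
                ]
                block_trials.extend((f, int(k)) for k in ids)
            rng.shuffle(block_trials)
            for trial_index, (f, pair_id) in enumerate(block_trials):
                p = pairs[pair_id]
                rows.append(
                    {
                        "subject": subject_id,
                        "block": block_index,
                        "trial": trial_index,
                        "stimulus_type": st,
                        "filter": f,
                        "pair_id": pair_id,
                        "is_same": p.is_same,
                        "probe_identity": p.probe[0],
                        "probe_image": p.probe[1],
                        "target_identity": p.target[0],
                        "target_image": p.target[1],
                    }
                )
            block_index += 1
    return pd.DataFrame(rows)
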