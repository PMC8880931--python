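"""Eligibility filtering and same-patient pair sampling.

Pre-training batches hold 2N ECGs from N distinct patients: for each
patient in a batch, two distinct records are drawn uniformly over the
patient's unordered record pairs, regardless of acquisition time or
intervening health change. Patients with a single record carry no
positive pair and are filtered out beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PairingError, UnfilteredCohortError


@dataclass
class ContrastiveBatch:
    """2N tensors from N distinct patients with explicit pair structure.

    ``pair_index[p] = (p1, p2)`` gives the in-batch positions of patient
    p's two ECGs.
    """

    tensors: list
    pair_index: np.ndarray
    n_patients: int

    def __post_init__(self):
        self.pair_index = np.asarray(self.pair_index, dtype=int)
        self.validate()

    def validate(self) -> None:
        n = self.n_patients
        if self.pair_index.shape != (n, 2):
            raise PairingError(
                f"pair_index shape {self.pair_index.shape} != ({n}, 2)")
        if len(self.tensors) != 2 * n:
            raise PairingError(
                f"batch holds {len(self.tensors)} tensors, expected {2 * n}")
        flat = self.pair_index.ravel()
        if sorted(flat.tolist()) != list(range(2 * n)):
            raise PairingError("pair positions must partition 0..2N-1")
        pids = [t.patient_id for t in self.tensors]
        seen = set()
        for p1, p2 in self.pair_index:
            if pids[p1] != pids[p2]:
                raise PairingError(
                    f"pair ({p1}, {p2}) mixes patients "
                    f"{pids[p1]!r} and {pids[p2]!r}")
            if pids[p1] in seen:
                raise PairingError(f"patient {pids[p1]!r} appears twice")
            seen.add(pids[p1])

    def stack(self) -> np.ndarray:
        """(2N, length, leads) array in batch position order."""
        return np.stack([t.values for t in self.tensors])


def filter_eligible(groups):
    """Retain patients with at least two records; order preserved."""
    return [g for g in groups if len(g.records) >= 2]


def draw_pair(rng: np.random.Generator, n_records: int) -> tuple:
    """Two distinct record indices, uniform over unordered pairs."""
    i, j = rng.choice(n_records, size=2, replace=False)
    return int(i), int(j)


def sample_batches(groups, n_patients_per_batch: int, seed: int,
                   epoch: int = 0):
    """Yield one epoch of contrastive batches, reproducible from
    (seed, epoch).

    Patients are permuted and chunked; a trailing incomplete chunk is
    dropped so every batch keeps the exact 2N structure. Each patient in
    a batch contributes two records drawn uniformly without replacement.
    """
    for g in groups:
        if len(g.records) < 2:
            raise UnfilteredCohortError(
                f"patient {g.patient_id!r} has {len(g.records)} record(s); "
                "run filter_eligible first")
    if n_patients_per_batch < 1:
        raise PairingError("n_patients_per_batch must be >= 1")
    if n_patients_per_batch > len(groups):
        raise PairingError(
            f"n_patients_per_batch={n_patients_per_batch} exceeds the "
            f"{len(groups)} eligible patients")
    rng = np.random.default_rng([seed, epoch])
    perm = rng.permutation(len(groups))
    n_full = len(groups) // n_patients_per_batch
    for b in range(n_full):
        chunk = perm[b * n_patients_per_batch:(b + 1) * n_patients_per_batch]
        tensors, pair_index = [], []
        for k, gi in enumerate(chunk):
            g = groups[gi]
            i, j = draw_pair(rng, len(g.records))
            tensors.extend([g.records[i], g.records[j]])
            pair_index.append((2 * k, 2 * k + 1))
        yield ContrastiveBatch(tensors=tensors,
                               pair_index=np.array(pair_index),
                               n_patients=len(chunk))
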