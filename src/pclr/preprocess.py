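"""Raw-ECG to model-input preprocessing.

The contract is deliberately minimal: divide each lead's integer
microvolt amplitudes by 1,000 (millivolts), convert to 32-bit floats,
and linearly interpolate each lead from its native length onto 4,096
points spanning the same time extent, assembling a 4,096 x 12 matrix in
the fixed lead order I, II, III, AVR, AVL, AVF, V1-V6. No filtering,
detrending or artifact removal is applied — downstream models are meant
to see routine-quality signals as recorded.

The interpolation grid is endpoint-inclusive: target point k sits at
source index k*(L-1)/4095, so the first and last samples are preserved
exactly (up to the 1/1000 scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (InvalidSamplingRateError, MissingLeadError,
                     NonFiniteSignalError)
from .synthetic import LEAD_NAMES, SUPPORTED_RATES, Cohort, RawECG

TARGET_LENGTH = 4096


@dataclass
class ECGTensor:
    """Preprocessed record: (4096, 12) float32 matrix in millivolts."""

    values: np.ndarray
    record_id: str
    patient_id: str
    lead_order: tuple = LEAD_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.lead_order):
            raise ValueError(
                f"expected (n, {len(self.lead_order)}) matrix, "
                f"got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise NonFiniteSignalError(
                f"record {self.record_id!r} has non-finite values")


def _interp_lead(x: np.ndarray, n_out: int) -> np.ndarray:
    L = x.shape[0]
    if L == 1:
        return np.full(n_out, x[0])
    grid = np.arange(n_out) * ((L - 1) / (n_out - 1))
    return np.interp(grid, np.arange(L), x)


def preprocess_record(raw: RawECG, target_length: int = TARGET_LENGTH) -> ECGTensor:
    """Scale one raw record to mV and interpolate each lead to length 4,096."""
    if raw.sampling_rate not in SUPPORTED_RATES:
        raise InvalidSamplingRateError(
            f"record {raw.record_id!r}: sampling rate {raw.sampling_rate} Hz "
            f"not in {SUPPORTED_RATES}")
    cols = []
    for lead in LEAD_NAMES:
        if lead not in raw.leads:
            raise MissingLeadError(
                f"record {raw.record_id!r} is missing lead {lead!r}")
        x = np.asarray(raw.leads[lead], dtype=np.float64)
        if x.size == 0:
            raise MissingLeadError(
                f"record {raw.record_id!r}: lead {lead!r} is empty")
        if not np.all(np.isfinite(x)):
            raise NonFiniteSignalError(
                f"record {raw.record_id!r}: lead {lead!r} has non-finite "
                f"amplitudes")
        cols.append(_interp_lead(x / 1000.0, target_length))
    values = np.stack(cols, axis=1).astype(np.float32)
    return ECGTensor(values=values, record_id=raw.record_id,
                     patient_id=raw.patient_id)


@dataclass
class BatchPreprocessResult:
    """Order-preserving batch output with per-record failures kept, not
    silently dropped."""

    tensors: list
    failures: list = field(default_factory=list)   # (record_id, exception)

    def __iter__(self):
        return iter(self.tensors)

    def __len__(self):
        return len(self.tensors)

    def raise_if_failures(self) -> None:
        if self.failures:
            names = ", ".join(rid for rid, _ in self.failures)
            raise self.failures[0][1].__class__(
                f"{len(self.failures)} record(s) failed preprocessing: {names}")


def batch_preprocess(records, target_length: int = TARGET_LENGTH) -> BatchPreprocessResult:
    """Preprocess many records; failures are collected with record ids."""
    result = BatchPreprocessResult(tensors=[])
    for raw in records:
        try:
            result.tensors.append(preprocess_record(raw, target_length))
        except Exception as exc:   # noqa: BLE001 - reported, not swallowed
            result.failures.append((raw.record_id, exc))
    return result


def resample_tensor(tensor: ECGTensor, length: int) -> ECGTensor:
    """Linearly resample a preprocessed tensor to a shorter length.

    Desk-scale plumbing for small encoder instances; the model-input
    contract itself is always 4,096 samples.
    """
    cols = [_interp_lead(tensor.values[:, j].astype(np.float64), length)
            for j in range(tensor.values.shape[1])]
    return ECGTensor(values=np.stack(cols, axis=1).astype(np.float32),
                     record_id=tensor.record_id, patient_id=tensor.patient_id,
                     lead_order=tensor.lead_order)


@dataclass
class TensorGroup:
    """A patient's preprocessed records; the unit pair sampling works on."""

    patient_id: str
    records: list


def preprocess_cohort(cohort: Cohort, target_length: int = TARGET_LENGTH,
                      resample_to: int | None = None) -> list:
    """Preprocess a whole cohort into per-patient tensor groups.

    ``resample_to`` optionally shrinks tensors for small encoders.
    Raises on the first failing record (use :func:`batch_preprocess` for
    collect-and-report semantics).
    """
    groups = []
    for g in cohort:
        tensors = []
        for raw in g.records:
            t = preprocess_record(raw, target_length)
            if resample_to is not None:
                t = resample_tensor(t, resample_to)
            tensors.append(t)
        groups.append(TensorGroup(patient_id=g.patient_id, records=tensors))
    return groups
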