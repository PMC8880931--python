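"""Preprocess raw records into model inputs.

The contract: divide each lead's microvolt amplitudes by 1,000 and
linearly interpolate to 4,096 samples, giving a 4,096 x 12 float32
matrix in millivolts with a fixed lead order. Nothing else — no
filtering or artifact removal.
"""

import numpy as np

from pclr.preprocess import batch_preprocess, preprocess_record
from pclr.synthetic import generate_cohort

cohort = generate_cohort(2, 2, seed=3)
records = list(cohort.all_records())

tensor = preprocess_record(records[0])
raw_ii = records[0].leads["II"]
print(f"raw: {len(raw_ii)} samples at {records[0].sampling_rate} Hz, "
      f"integer uV; first value {raw_ii[0]} uV")
print(f"tensor: {tensor.values.shape} {tensor.values.dtype}, "
      f"first lead-II value {tensor.values[0, 1]:.3f} mV "
      f"(= {raw_ii[0]}/1000, endpoints preserved)")
print(f"lead order: {tensor.lead_order}")

bad = records[1]
del bad.leads["V6"]
result = batch_preprocess(records)
print(f"\nbatch of {len(records)}: {len(result.tensors)} tensors, "
      f"{len(result.failures)} failure(s)")
for rid, err in result.failures:
    print(f"  {rid}: {type(err).__name__}: {err}")
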