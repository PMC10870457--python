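"""The six numeric representations of one peptide window.

Composition encodings collapse the window to residue (or group)
frequencies; the positional encodings keep one row per window position.
"""

import numpy as np

from kcrnet import get_encoder

window = "LAVDESGRTMEAFN" + "K" + "QPWYHCIDXSTGEW"  # 29-mer, K at the center
for name in ("aac", "egaac", "be", "we", "aaindex", "blosum62"):
    m = np.asarray(get_encoder(name)(window))
    print(f"{name:>9}: shape {m.shape}  first values {np.round(m.ravel()[:5], 3)}")
# aac sums to 1 (residue frequencies); egaac covers the five physicochemical
# groups (X counts toward none); be is one-hot per position; we gives the
# integer vocabulary IDs consumed by the trainable embedding; aaindex holds
# 29 scaled physicochemical indices per residue; blosum62 the raw
# substitution-score rows.
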