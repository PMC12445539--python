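"""Score and decode tag sequences with the linear-chain CRF.

Shows the unnormalized path score, the log-partition from the forward
algorithm, the resulting sequence probability, and Viterbi decoding.
"""

import math

import numpy as np

from flcnn import CRFParams, log_partition, nll_loss, sequence_score, viterbi_decode

# 3 positions, 3 tags (O, B-SYM, I-SYM); emissions favour B at 0, I at 1
emissions = np.array([[0.2, 2.0, -1.0],
                      [0.1, -0.5, 1.8],
                      [1.5, 0.0, 0.3]])
params = CRFParams(
    transitions=np.array([[0.5, 0.0, -2.0],   # O  -> O/B/I
                          [-0.5, -0.5, 1.0],  # B  -> ...
                          [0.0, -0.5, 0.5]]), # I  -> ...
    start_weights=np.array([0.2, 0.1, -2.0]),
    end_weights=np.zeros(3),
)

gold = [1, 2, 0]  # B-SYM I-SYM O
score = sequence_score(emissions, gold, params)
logz = log_partition(emissions, params)
print(f"gold path score (log-potential): {score:.4f}")
print(f"log partition over all 27 paths: {logz:.4f}")
print(f"p(gold | x) = exp(score - logZ) = {math.exp(score - logz):.4f}")
print(f"negative log-likelihood: {nll_loss(emissions, gold, params):.4f}")

tags, best = viterbi_decode(emissions, params)
print(f"Viterbi decode: {tags} with score {best:.4f}"
      f" ({'matches' if tags == gold else 'differs from'} the gold path)")
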