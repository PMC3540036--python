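"""Score a promoter with a frequency matrix.

Builds a small motif, scans a promoter on both strands, and prints the
best-scoring site placements and the motif's information content.
"""

import numpy as np

from promsig import (BackgroundModel, load_frequency_matrix,
                     motif_information, scan_scores)

# A 6-bp motif as a whitespace table (counts are auto-detected and
# normalised; probabilities work too).
MATRIX = """
A C G T
12  1  1  1
 1 12  1  1
 1  1 12  1
 1  1  1 12
 1  1  1 12
 1  1 12  1
"""

matrix = load_frequency_matrix(MATRIX, name="toy")
bg = BackgroundModel(gc=0.38)

promoter = "TTATAGCAACGTTGGCATTTAACGTTGATTACCGGT"
track = scan_scores(matrix, bg, promoter)

print(f"motif {matrix.consensus()} information "
      f"{motif_information(matrix, bg):.2f} nats")
print("top site placements (0-based start, strand, log2 odds):")
order = np.argsort(track.ravel())[::-1][:3]
for flat in order:
    pos, strand = divmod(flat, 2)
    print(f"  {pos:3d}  {'+-'[strand]}  {track[pos, strand]:6.2f}")
# A positive score marks a subsequence the factor prefers over background;
# each unit is a twofold preference.
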