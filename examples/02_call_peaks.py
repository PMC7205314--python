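"""Call Ago-binding peaks from a pile of crosslinked reads.

Thirty fragments containing a 6-nt site on a 2-kb transcript, plus scattered
background reads: the site becomes a significant Poisson peak whose spline
summit sits at the site center.
"""

import numpy as np
import pandas as pd

from clearclip.peaks import call_peaks

rng = np.random.Generator(np.random.PCG64(0))
tlen, center = 2000, 1000
rows = []
for i in range(30):  # fragments all contain the 6-nt site
    flen = int(rng.integers(35, 50))
    start = int(rng.integers(center + 3 - flen, center - 2))
    rows.append((f"site{i}", "tx", start, start + flen, 1))
for i in range(15):  # uniform background
    s = int(rng.integers(0, tlen - 45))
    rows.append((f"bg{i}", "tx", s, s + 45, 1))
clip = pd.DataFrame(rows, columns=["read_id", "transcript_id", "start", "end", "dup_count"])

peaks = call_peaks(clip, pd.DataFrame(), {"tx": tlen})
for p in peaks[peaks.significant].itertuples():
    print(
        f"peak at {p.summit:.1f} (true site center {center}), "
        f"height {p.height:.1f} reads, p = {p.pvalue:.2e}"
    )
# The summit lands within a few nt of the planted site; background read
# clusters stay non-significant under the uniform Poisson null.
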