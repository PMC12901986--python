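"""Long-read emulation over a fragment pool.

The modelled library prep polyadenylates every fragment and primes reverse
transcription from the (possibly artificial) poly-A tail, so the 3' end of
a fragment is always captured while the 5' end may be lost. Reads are
therefore sub-intervals of fragments truncated only on the 5' side:

* with probability ``full_length_prob`` the read spans the whole fragment;
* otherwise, if the fragment 5' end is a cleaved end, a geometric number
  of nucleotides (mean ``cleaved_end_trim_mean``) is resected — this is
  what turns recurrent cut positions into 10-20 nt coverage dips;
* otherwise (native 5' end) a uniform fraction up to
  ``native_truncation_frac`` of the fragment is lost, emulating RT fall-off.

All emitted records are primary, forward-strand, transcript-space.
"""

from __future__ import annotations

import warnings

import numpy as np

from .._rng import rng_from_seed
from ..alignments import AlignmentRecord, AlignmentSet
from ..errors import ValidationError
from .cleavage import FragmentPool

__all__ = ["simulate_read_alignments"]


def simulate_read_alignments(
    pool: FragmentPool,
    depth: float,
    full_length_prob: float = 0.9,
    seed: int = 0,
    cleaved_end_trim_mean: float = 30.0,
    native_truncation_frac: float = 0.25,
) -> AlignmentSet:
    """Sample reads from a fragment pool.

    ``depth`` is the mean number of reads per fragment (Poisson). Returns
    an empty set with a warning when the pool is empty.
    """
    if depth <= 0:
        raise ValidationError("depth must be > 0")
    if not (0.0 <= full_length_prob <= 1.0):
        raise ValidationError("full_length_prob must be in [0, 1]")
    if cleaved_end_trim_mean < 1.0:
        raise ValidationError("cleaved_end_trim_mean must be >= 1")
    if not pool.fragments:
        warnings.warn("empty fragment pool: returning empty AlignmentSet")
        return AlignmentSet([], dict(pool.transcript_lengths))

    rng = rng_from_seed(seed)
    geom_p = 1.0 / cleaved_end_trim_mean
    records: list[AlignmentRecord] = []
    read_i = 0
    n_reads_per_frag = rng.poisson(depth, size=len(pool.fragments))
    for frag, n_reads in zip(pool.fragments, n_reads_per_frag):
        if n_reads == 0:
            continue
        cleaved_start = frag.start > 0
        for _ in range(int(n_reads)):
            start = frag.start
            if rng.random() >= full_length_prob:
                if cleaved_start:
                    trim = int(rng.geometric(geom_p))
                else:
                    trim = int(rng.uniform(0.0, native_truncation_frac) * frag.length)
                start = min(frag.start + trim, frag.end - 1)
            records.append(
                AlignmentRecord(
                    read_id=f"read_{read_i:08d}",
                    transcript_id=frag.transcript_id,
                    tstart=start,
                    tend=frag.end,
                    is_primary=True,
                    mapq=60,
                    strand="+",
                )
            )
            read_i += 1
    return AlignmentSet(records, dict(pool.transcript_lengths))
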