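"""Writing and reading 2bit genome archives.

Builds a tiny synthetic genome, writes it as a *.2bit archive, and
extracts subsequences with and without soft-masking.
"""

import tempfile
from pathlib import Path

from goldenpath import fixtures, open_archive

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.2bit"
    spec = fixtures.FixtureSpec(seed=1, chrom_sizes={"chr1": 600, "chrM": 120})
    truth = fixtures.make_genome_2bit(path, spec)

    arc = open_archive(path)
    print(f"archive holds {len(arc.names)} sequences: {arc.names}")
    # center a 60 bp window on the first soft-masked base so the case
    # handling is visible
    lo = max(0, next(i for i, c in enumerate(truth["chr1"]) if c.islower()) - 20)
    window = arc.subseq("chr1", lo, lo + 60)                # soft-masked (default)
    unmasked = arc.subseq("chr1", lo, lo + 60, masked=False)
    print(f"chr1:{lo + 1}-{lo + 60} masked:   {window}")
    print(f"chr1:{lo + 1}-{lo + 60} unmasked: {unmasked}")
    print("lowercase = repeat-masked bases; N = unknown bases")
    assert window == truth["chr1"][lo : lo + 60]  # matches the generator's truth
    print("extraction matches the generating sequence exactly")
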