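"""Intervals and the hierarchical bin index.

Parses a browser-style interval string, shows the coordinate-convention
conversion, and computes which bins the UCSC bin index assigns and
scans for the interval.
"""

from goldenpath import bin_from_interval, bins_overlapping, format_interval, parse_interval

# The browser displays 1-based fully-closed coordinates; the database
# stores 0-based half-open ones.  parse_interval absorbs the difference.
iv = parse_interval("chr1:123,456-456,789")
print(f"parsed {format_interval(iv)!r}: internal start={iv.start}, end={iv.end}, "
      f"length={iv.length()} bp")

# A stored feature goes into the smallest bin that encompasses it; a
# query scans every bin that could hold an overlapping feature.
smallest = bin_from_interval(iv.start, iv.end)
candidates = bins_overlapping(iv.start, iv.end)
print(f"smallest enclosing bin: {smallest}")
print(f"query touches {len(candidates)} of 4681 bins: {candidates}")
print("-> a SQL interval query only scans rows in those bins, never the whole table")
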