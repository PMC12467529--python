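"""Score the packaged eight-feature reference record and print every
intermediate of the chain.

The table shows, per feature: the distance ratios rTC/rTA, the binary
entropy H of that pair, the per-record weight W, the weighted distance-gap
component owoD and its min-max-normalized value.  The record is classified
positive (dementia-like profile) because its aggregate OWOD does not exceed
the cut-off score of the threshold pseudo-record.
"""

from owod import format_worked_example

print(format_worked_example())
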