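# Tissue-class legend for a Zubal head phantom raw volume.
#
# Label ids differ between distributions of the phantom; check this mapping
# against the legend text shipped with your copy before use.  Classes must
# come from: air, skull, gray_matter, white_matter, ventricle_csf,
# striatum (side-unsplit; split at the midline on extraction),
# striatum_left, striatum_right, other.
0: air
1: other          # skin
2: ventricle_csf  # cerebral fluid / spinal cord
3: other
4: skull
5: other          # spine
6: white_matter
7: gray_matter
8: striatum       # caudate nucleus
9: striatum       # putamen
10: ventricle_csf # lateral ventricles
11: ventricle_csf # third ventricle
12: ventricle_csf # fourth ventricle / aqueduct
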