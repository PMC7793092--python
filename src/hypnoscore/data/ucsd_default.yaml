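# UCSD actigraphy scoring algorithm — default coefficients.
#
# Weighted 7-min span: the four preceding minutes, the scored minute, and
# the two following minutes (k = -4 ... +2).  An epoch is scored sleep when
# the weighted sum falls below the threshold.  PIM-mode coefficients from
# Jean-Louis et al. (2001), J Neurosci Methods 105:185-191.
version: 1
name: ucsd-pim-2001
count_mode: PIM
weights: [0.0064, 0.0074, 0.0112, 0.0112, 0.0118, 0.0069, 0.0046]
threshold: 1.0
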