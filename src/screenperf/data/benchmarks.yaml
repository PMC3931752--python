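# BCSC screening-mammography benchmarks.
# threshold / reference_median are proportions (CDR per-exam, RR per-exam).
# inadequate_strict: an interval touching the threshold from the unfavorable
# side is classified uncertain, not inadequate (strict inequality).
benchmarks:
  - metric_name: CDR
    threshold: 0.0024        # 10th percentile, 2.4 per 1000
    direction: higher_is_better
    confidence: 0.95
    reference_median: 0.0044 # 4.4 per 1000
  - metric_name: RR
    threshold: 0.168         # 90th percentile, 16.8%
    direction: lower_is_better
    confidence: 0.95
    reference_median: 0.097  # 9.7%
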