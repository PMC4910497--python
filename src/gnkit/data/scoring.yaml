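# Point weights for match features and the sigmoid base.
# Calibrated so that the confidence printed for the four reference cases
# is reproduced exactly: uninomial exact 0.75, binomial canonical 0.988,
# binomial + agreeing authorship 0.999, authorship conflict 0.75, and an
# edit-distance-2 binomial lands on the 0.5 human-check boundary.
sigmoid_base: 3.0
points:
  uninomial: 1.0
  binomial: 4.0
  trinomial_plus: 4.0
  authorship_agrees: 2.3
  authorship_conflicts: -3.0
  per_edit: -2.0
  multi_target: -1.0
human_check_threshold: 0.5
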