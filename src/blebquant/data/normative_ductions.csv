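direction,degrees
elevation,43
depression,57
adduction,45
abduction,46
elevation_in_abduction,45
elevation_in_adduction,40
depression_in_abduction,53
depression_in_adduction,52
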