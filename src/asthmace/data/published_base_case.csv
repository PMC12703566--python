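# Published base-case incremental-analysis surfaces (total cost in GBP and
# effect per strategy, by effect block) of the EINSTEIN cost-utility
# analysis, as printed. Used to verify the incremental module's arithmetic
# and dominance classification against the published table. The 377 printed
# for ics_ltra in the controlled_days block is the published figure (the
# QALY block prints 596 for the same strategy).
block,strategy,cost,effect
qaly,ics_laba,501,0.9512
qaly,medium_dose_ics,377,0.9508
qaly,low_dose_ics,284,0.9504
qaly,high_dose_ics,470,0.9503
qaly,ics_ltra,596,0.9495
qaly,ltra,670,0.9366
controlled_days,ics_laba,501,335.6
controlled_days,medium_dose_ics,377,334.6
controlled_days,low_dose_ics,284,333.5
controlled_days,ltra,670,293.8
controlled_days,high_dose_ics,470,332.2
controlled_days,ics_ltra,377,331.5
exacerbation_free_days,medium_dose_ics,377,361.8
exacerbation_free_days,low_dose_ics,284,361.5
exacerbation_free_days,high_dose_ics,470,362.4
exacerbation_free_days,ics_laba,501,362.2
exacerbation_free_days,ics_ltra,377,360.0
exacerbation_free_days,ltra,670,350.8
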