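# Default parameter bounds by unit class.  Upper bounds are set two orders
# of magnitude above a physiologic scale for the class; edit here to widen
# or narrow every model's prior support at once.
rate:            {lower: 0.0,   upper: 10.0}     # 1/day
signed_rate:     {lower: -10.0, upper: 10.0}     # 1/day, sign free
concentration:   {lower: 0.0,   upper: 1000.0}   # ug/L
fraction:        {lower: 0.0,   upper: 1.0}      # dimensionless in [0,1]
dimensionless:   {lower: 0.0,   upper: 10.0}     # dimensionless, order 1
flux:            {lower: 0.0,   upper: 100.0}    # ug/L/day
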