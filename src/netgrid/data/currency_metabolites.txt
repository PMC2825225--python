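# Default currency-metabolite stoplist.
# One identifier per line; '#' starts a comment. Edit or replace freely —
# which metabolites count as "currency" depends on the reconstruction's
# naming scheme and on the analysis at hand.
h2o
co2
atp
adp
pi
nadh
nad
nadph
nadp
h
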