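# Pre-negation trigger phrases, pseudo-negations and scope terminators.
# One phrase per line; phrases are normalized (lowercase, alphanumeric) at load.

[PRE]
no
not
without
denies
denied
deny
negative for
free of
absence of
absent
no evidence of
no history of
no signs of
no sign of
ruled out
rules out
rule out
never had
never developed
cannot
unremarkable for

[PSEUDO]
not only
no increase
no change
no further
not cause
not certain if
not certain whether
without difficulty
not necessarily

[TERM]
but
however
although
though
except
apart from
aside from
nevertheless
yet
still
which
secondary to
as a cause of
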