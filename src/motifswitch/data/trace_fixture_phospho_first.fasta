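>HUMAN|tau_like_HUMAN
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVPAGPGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CHIMP|tau_like_CHIMP
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVPAGPGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>MOUSE|tau_like_MOUSE
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVPAGPGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>RATUS|tau_like_RATUS
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVPAGPGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>BOVIN|tau_like_BOVIN
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVPAGPGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CHICK|tau_like_CHICK
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVPAGPGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>XENTR|tau_like_XENTR
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVPAGPGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>DANRE|tau_like_DANRE
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CIONA|tau_like_CIONA
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>DROME|tau_like_DROME
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLTGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>ANOGA|tau_like_ANOGA
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CAEEL|tau_like_CAEEL
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>YEAST|tau_like_YEAST
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>DICDI|tau_like_DICDI
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>ARATH|tau_like_ARATH
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>PLAFA|tau_like_PLAFA
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
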