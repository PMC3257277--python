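>HUMAN|cdkn1b_like_HUMAN
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLYGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CHIMP|cdkn1b_like_CHIMP
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLYGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>MOUSE|cdkn1b_like_MOUSE
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLYGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>RATUS|cdkn1b_like_RATUS
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLYGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>BOVIN|cdkn1b_like_BOVIN
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CHICK|cdkn1b_like_CHICK
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>XENTR|cdkn1b_like_XENTR
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>DANRE|cdkn1b_like_DANRE
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CIONA|cdkn1b_like_CIONA
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>DROME|cdkn1b_like_DROME
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>ANOGA|cdkn1b_like_ANOGA
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>CAEEL|cdkn1b_like_CAEEL
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVRPAKGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>YEAST|cdkn1b_like_YEAST
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>DICDI|cdkn1b_like_DICDI
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>ARATH|cdkn1b_like_ARATH
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
>PLAFA|cdkn1b_like_PLAFA
MGSAQDLVNHECWITAFGQNDLSAVMHQIGCEWTANDSLVGAGAGSAHQLAGAHQNIVDC
LESWMTAGFNQHDLVACISEWGTMNQAHDLV
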