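code,name,category
U,Upside-down,non_interactive
B,Bobbing,non_interactive
G,Grooming,non_interactive
I,Immobilized,high_intensity_aggression
J,Jump,non_interactive
T,Turn toward,interactive_nonaggressive
H,Hold,high_intensity_aggression
Wr,Wrestle,high_intensity_aggression
Av,Avoid,interactive_nonaggressive
W,Walking,non_interactive
Ap,Approach,interactive_nonaggressive
Lo,Low-intensity aggression,low_intensity_aggression
L,Lunge,high_intensity_aggression
R,Retreat,interactive_nonaggressive
Sti,Stilt,non_interactive
Sta,Standing,non_interactive
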