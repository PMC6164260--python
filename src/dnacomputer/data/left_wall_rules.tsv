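# Transition rules of the left-wall-following maze robot.
# Columns: state  input-signal  next-state
# States: F (forward), L (rotate left), R (rotate right)
# Signals: f (wall ahead), f_bar (no wall ahead), l_bar (no wall on left), l (wall on left)
F	f	R
F	f_bar	F
F	l_bar	L
F	l	F
L	l_bar	L
L	l	F
R	f	R
R	f_bar	F
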