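;;; Built-in ARPABET pronunciation lexicon (CMU-dict text dialect).
;;; Covers the one-word response vocabulary plus common utterance-initial
;;; words and filler tokens used by the synthetic dyad generator. Entries
;;; follow North American CMU-dict conventions; MMHMM is an artifact
;;; convention for the vocalized nasal backchannel (no dictionary entry
;;; exists), judged on its /m/ onset.
ACTUALLY  AE2 K CH UW0 AH0 L IY0
ALRIGHT  AO0 L R AY1 T
AND  AH0 N D
BUT  B AH1 T
DO  D UW1
EXCELLENT  EH1 K S AH0 L AH0 N T
GOOD  G UH1 D
HE  HH IY1
I  AY1
IT  IH1 T
KNOW  N OW1
MAYBE  M EY1 B IY0
MMHMM  M HH M
NEXT  N EH1 K S T
NICE  N AY1 S
NO  N OW1
NOT  N AA1 T
OF  AH0 V
OH  OW1
OK  OW2 K EY1
OKAY  OW2 K EY1
ONE  W AH1 N
REALLY  R IH1 L IY0
RIGHT  R AY1 T
SHE  SH IY1
SO  S OW1
SURE  SH UH1 R
THANKS  TH AE1 NG K S
THAT  DH AE1 T
THAT'S  DH AE1 T S
THE  DH AH0
THEN  DH EH1 N
THERE  DH EH1 R
THEY  DH EY1
THIS  DH IH1 S
TO  T UW1
TRUE  T R UW1
VERY  V EH1 R IY0
WAS  W AA1 Z
WE  W IY1
WELL  W EH1 L
WHAT  W AH1 T
WHEN  W EH1 N
WHICH  W IH1 CH
YEAH  Y AE1
YEP  Y EH1 P
YES  Y EH1 S
YOU  Y UW1
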