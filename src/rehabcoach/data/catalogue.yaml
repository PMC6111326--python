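# Default exercise catalogue: the senior exercise programme, all four groups.
#
# The first 15 entries are the sequence-recognizer classes, in confusion
# matrix row order.  Canonical sequences over pose ids 1-9 follow the
# documented seated capture protocol (e.g. arm raises: arms by sides ->
# middle torso -> over head -> middle torso -> by sides).  The remaining
# vocabularies are this package's own design: left/right sibling exercises
# share their endpoint (neutral) pose so that the two variants differ only
# in the middle pose, which is what makes them the hardest pair to tell
# apart, mirroring the recognizer's observed confusion structure.
- name: upper body twist left
  group: sitting
  canonical: [4, 5, 4]
  restrictions: [torso]
- name: upper body twist right
  group: sitting
  canonical: [4, 6, 4]
  restrictions: [torso]
- name: hip marching left
  group: sitting
  canonical: [7, 8, 7]
  restrictions: [legs]
- name: hip marching right
  group: sitting
  canonical: [7, 9, 7]
  restrictions: [legs]
- name: arm raises
  group: sitting
  canonical: [1, 2, 3, 2, 1]
  restrictions: [shoulders]
- name: neck stretch left
  group: sitting
  canonical: [10, 11, 10]
  restrictions: [neck]
- name: neck stretch right
  group: sitting
  canonical: [10, 12, 10]
  restrictions: [neck]
- name: sit to stand
  group: strength
  canonical: [36, 13, 36]
  restrictions: [legs]
- name: mini squats
  group: strength
  canonical: [13, 14, 13]
  restrictions: [legs, knees]
- name: sideways leg lift
  group: strength
  canonical: [33, 15, 33]
  restrictions: [legs, balance]
- name: leg extension
  group: strength
  canonical: [37, 16, 37]
  restrictions: [legs, knees]
- name: bicep curls
  group: strength
  canonical: [34, 17, 34]
  restrictions: [arms]
- name: sideways bend
  group: flexibility
  canonical: [35, 18, 35]
  restrictions: [torso]
- name: simple grapevine
  group: balance
  canonical: [13, 19, 20, 19, 13]
  restrictions: [legs, balance]
- name: heel to toe walk
  group: balance
  canonical: [13, 21, 22, 21, 13]
  restrictions: [legs, balance]
# Remaining programme exercises (not recognizer classes); generic two-sided
# forms cover both directions in one repetition.
- name: chest stretch
  group: sitting
  canonical: [13, 23, 13]
  restrictions: [shoulders]
- name: upper body twist
  group: sitting
  canonical: [4, 5, 4, 6, 4]
  restrictions: [torso]
- name: hip marching
  group: sitting
  canonical: [7, 8, 7, 9, 7]
  restrictions: [legs]
- name: ankle stretch
  group: sitting
  canonical: [7, 24, 7]
  restrictions: [legs]
- name: neck rotation
  group: sitting
  canonical: [10, 25, 10, 26, 10]
  restrictions: [neck]
- name: neck stretch
  group: sitting
  canonical: [10, 11, 10, 12, 10]
  restrictions: [neck]
- name: calf stretch
  group: flexibility
  canonical: [13, 27, 13]
  restrictions: [legs]
- name: calf raises
  group: strength
  canonical: [13, 28, 13]
  restrictions: [legs, balance]
- name: wall press up
  group: strength
  canonical: [13, 32, 13]
  restrictions: [arms, shoulders]
- name: sideways walking
  group: balance
  canonical: [13, 29, 13, 29, 13]
  restrictions: [legs, balance]
- name: step up
  group: balance
  canonical: [13, 30, 13]
  restrictions: [legs, balance]
- name: one leg stand
  group: balance
  canonical: [13, 31, 13]
  restrictions: [legs, balance]
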