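# Pose-class alphabet.  Id 0 is reserved for padding and must not appear.
# Ids 1-9 are the nine seated pose classes of the original capture protocol;
# the rest extend the alphabet to cover the standing and balance exercises.
- {id: 1, description: sit upright with arms by sides}
- {id: 2, description: sit upright with arms up to middle torso height}
- {id: 3, description: sit upright with arms over head}
- {id: 4, description: sit upright with crossing arms reaching shoulders}
- {id: 5, description: sit upright with crossing arms reaching shoulders and upper body turned left}
- {id: 6, description: sit upright with crossing arms reaching shoulders and upper body turned right}
- {id: 7, description: sit upright held on the sides of the chair}
- {id: 8, description: sit upright held on the sides of the chair with left leg lifted}
- {id: 9, description: sit upright held on the sides of the chair with right leg lifted}
- {id: 10, description: sit upright with head facing forward}
- {id: 11, description: sit upright with head tilted towards the left shoulder}
- {id: 12, description: sit upright with head tilted towards the right shoulder}
- {id: 13, description: stand upright with arms by sides}
- {id: 14, description: stand with knees bent in a shallow squat}
- {id: 15, description: stand with one leg raised out to the side}
- {id: 16, description: sit upright with one leg extended straight out}
- {id: 17, description: stand with forearms curled up to the shoulders}
- {id: 18, description: stand leaning sideways with one arm sliding down the thigh}
- {id: 19, description: stand mid side-step with legs apart}
- {id: 20, description: stand with legs crossed mid grapevine step}
- {id: 21, description: stand heel-to-toe with feet in line}
- {id: 22, description: stand mid step with the rear foot moving to the front}
- {id: 23, description: stand with arms pressed back opening the chest}
- {id: 24, description: sit upright with toes lifted and heel on the floor}
- {id: 25, description: sit upright with head turned to the left}
- {id: 26, description: sit upright with head turned to the right}
- {id: 27, description: stand in a lunge with the rear calf stretched}
- {id: 28, description: stand on tiptoes with heels raised}
- {id: 29, description: stand mid sideways step}
- {id: 30, description: stand with one foot placed on a step}
- {id: 31, description: stand balanced on one leg}
- {id: 32, description: lean towards a wall with elbows bending}
- {id: 33, description: stand holding the back of a chair}
- {id: 34, description: stand with a weight held in each hand by the sides}
- {id: 35, description: stand with feet hip-width apart and arms hanging}
- {id: 36, description: sit on the edge of the chair with feet drawn back}
- {id: 37, description: sit upright with both hands resting on the thighs}
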