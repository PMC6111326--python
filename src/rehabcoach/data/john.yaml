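# Default simulation persona: a broadly healthy elderly user with a slight
# leg problem (lower means on leg-loaded exercises), one clearly declining
# exercise (step up) and one chronically low one (sideways bend).
# abilities: exercise -> [mean %, sd %]; trends: per-iteration drift in %.
# The six left/right split variants are excluded so a study runs over the
# 21 generically named programme exercises.
name: john
abilities:
  chest stretch: [65, 20]
  upper body twist: [70, 18]
  hip marching: [60, 22]
  ankle stretch: [50, 15]
  arm raises: [55, 25]
  neck rotation: [60, 25]
  neck stretch: [55, 20]
  sideways bend: [14, 5]
  calf stretch: [55, 18]
  sit to stand: [45, 15]
  mini squats: [45, 18]
  calf raises: [55, 30]
  sideways leg lift: [40, 10]
  leg extension: [55, 15]
  wall press up: [60, 17]
  bicep curls: [45, 25]
  sideways walking: [55, 12]
  simple grapevine: [60, 25]
  heel to toe walk: [60, 25]
  one leg stand: [65, 18]
  step up: [80, 8]
trends:
  step up: -0.7
excluded:
  - upper body twist left
  - upper body twist right
  - hip marching left
  - hip marching right
  - neck stretch left
  - neck stretch right
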