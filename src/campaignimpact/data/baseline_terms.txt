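diet
dieting
health
healthy
nutrition
fitness
wellness
calories
weight
exercise
workout
vegan
vegetarian
keto
protein
fasting
gym
selfcare
mealprep
wellbeing
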