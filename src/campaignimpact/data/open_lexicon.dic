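%
1	Female
2	Anxiety
3	Risk
4	Money
5	Body
6	Health
7	Ingest
8	Friend
9	Posemo
%
women	1
woman	1
she	1
her	1
hers	1
herself	1
girl	1
girls	1
lady	1
ladies	1
female	1
females	1
mother	1
mom	1
daughter	1
sister	1
wife	1
aunt	1
grandma	1
queen	1
femin*	1
anxiety	2
anxious	2
worry	2
worried	2
worries	2
worr*	2
nervous	2
stress	2
stressed	2
stressful	2
afraid	2
fear*	2
scared	2
panic	2
tense	2
uneasy	2
upset	2
overwhelm*	2
dread	2
risk	3
risks	3
risky	3
danger*	3
beware	3
caution*	3
apprehension	3
apprehensive	3
threat*	3
unsafe	3
hazard*	3
warning	3
avoid*	3
doubt*	3
concern*	3
money	4
cash	4
pay	4
paid	4
paying	4
price*	4
cost*	4
dollar*	4
profit*	4
economy	4
economic	4
market*	4
invest*	4
bank*	4
budget*	4
salary	4
debt*	4
tax*	4
wealth*	4
job	4
jobs	4
body	5
bodies	5
skin	5
arm	5
arms	5
leg	5
legs	5
face	5
hair	5
head	5
hand	5
hands	5
heart	5
stomach	5
muscle*	5
bone*	5
weight	5
fat	5
thin	5
hips	5
waist	5
chest	5
health	6
healthy	6
unhealthy	6
doctor*	6
nurse*	6
hospital*	6
medicine	6
medical	6
clinic*	6
therapy	6
therapist*	6
ill	6
illness	6
sick	6
symptom*	6
diagnos*	6
treatment*	6
wellness	6
virus*	6
pandemic	6
vaccine*	6
flu	6
infection*	6
recovery	6
eat	7
eats	7
eating	7
ate	7
food*	7
meal*	7
snack*	7
breakfast	7
lunch	7
dinner	7
drink*	7
hungry	7
hunger	7
diet*	7
cook*	7
taste*	7
chew*	7
swallow*	7
nutriti*	7
friend*	8
buddy	8
buddies	8
pal	8
pals	8
companion*	8
neighbor*	8
roommate*	8
bestie*	8
mate	8
mates	8
love*	9
happy	9
happiness	9
joy*	9
hope*	9
glad	9
great	9
good	9
awesome	9
wonderful	9
amazing	9
beautiful	9
excited	9
excitement	9
proud	9
grateful	9
thankful	9
support*	9
kind	9
kindness	9
brave	9
courage	9
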