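mary	f
patricia	f
jennifer	f
linda	f
elizabeth	f
barbara	f
susan	f
jessica	f
sarah	f
karen	f
nancy	f
lisa	f
margaret	f
betty	f
sandra	f
ashley	f
dorothy	f
kimberly	f
emily	f
donna	f
michelle	f
carol	f
amanda	f
melissa	f
deborah	f
stephanie	f
rebecca	f
laura	f
sharon	f
cynthia	f
kathleen	f
amy	f
shirley	f
angela	f
helen	f
anna	f
brenda	f
pamela	f
nicole	f
ruth	f
katherine	f
samantha	f
christine	f
emma	f
catherine	f
debra	f
virginia	f
rachel	f
carolyn	f
janet	f
maria	f
heather	f
diane	f
julie	f
joyce	f
victoria	f
kelly	f
christina	f
lauren	f
joan	f
evelyn	f
olivia	f
judith	f
megan	f
cheryl	f
martha	f
andrea	f
frances	f
hannah	f
jacqueline	f
ann	f
gloria	f
jean	f
kathryn	f
alice	f
teresa	f
sara	f
janice	f
doris	f
madison	f
julia	f
grace	f
judy	f
abigail	f
marie	f
denise	f
beverly	f
amber	f
theresa	f
marilyn	f
danielle	f
diana	f
brittany	f
natalie	f
sophia	f
rose	f
isabella	f
alexis	f
kayla	f
charlotte	f
brigitte	f
yelena	f
fiona	f
priya	f
amara	f
ingrid	f
james	m
robert	m
john	m
michael	m
william	m
david	m
richard	m
joseph	m
thomas	m
charles	m
christopher	m
daniel	m
matthew	m
anthony	m
mark	m
donald	m
steven	m
paul	m
andrew	m
joshua	m
kenneth	m
kevin	m
brian	m
george	m
edward	m
ronald	m
timothy	m
jason	m
jeffrey	m
ryan	m
jacob	m
gary	m
nicholas	m
eric	m
jonathan	m
stephen	m
larry	m
justin	m
scott	m
brandon	m
benjamin	m
samuel	m
gregory	m
frank	m
alexander	m
raymond	m
patrick	m
jack	m
dennis	m
jerry	m
tyler	m
aaron	m
jose	m
adam	m
henry	m
nathan	m
douglas	m
zachary	m
peter	m
kyle	m
walter	m
ethan	m
jeremy	m
harold	m
keith	m
christian	m
roger	m
noah	m
gerald	m
carl	m
terry	m
sean	m
austin	m
arthur	m
lawrence	m
jesse	m
dylan	m
bryan	m
joe	m
jordan	m
billy	m
bruce	m
albert	m
willie	m
gabriel	m
logan	m
alan	m
juan	m
wayne	m
roy	m
ralph	m
randy	m
eugene	m
vincent	m
russell	m
elijah	m
louis	m
bobby	m
philip	m
johnny	m
victor	m
marco	m
diego	m
omar	m
alex	f
alex	m
taylor	f
taylor	m
jamie	f
jamie	m
casey	f
casey	m
morgan	f
morgan	m
riley	f
riley	m
jordan	f
sam	f
sam	m
charlie	f
charlie	m
robin	f
robin	m
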