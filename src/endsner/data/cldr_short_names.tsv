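# CLDR English emoji short names (pinned subset, CLDR v44 annotations).
# Columns: emoji<TAB>short name.  Codepoints without an entry fall back to
# their Unicode character name.
🔥	fire
💨	dashing away
💯	hundred points
✨	sparkles
😍	smiling face with heart-eyes
😂	face with tears of joy
🤣	rolling on the floor laughing
😊	smiling face with smiling eyes
😎	smiling face with sunglasses
😋	face savoring food
🤤	drooling face
😜	winking face with tongue
🙌	raising hands
👌	OK hand
👍	thumbs up
👊	oncoming fist
✌	victory hand
🙏	folded hands
💪	flexed biceps
❤	red heart
💙	blue heart
💚	green heart
💜	purple heart
🖤	black heart
💛	yellow heart
🧡	orange heart
💕	two hearts
💦	sweat droplets
🍉	watermelon
🍓	strawberry
🍇	grapes
🍑	peach
🍒	cherries
🍍	pineapple
🥭	mango
🍋	lemon
🍊	tangerine
🍎	red apple
🍏	green apple
🫐	blueberries
🍌	banana
🍬	candy
🍭	lollipop
🍦	soft ice cream
🍨	ice cream
🎂	birthday cake
🍰	shortcake
🧁	cupcake
🍩	doughnut
🍪	cookie
🥤	cup with straw
🧃	beverage box
☕	hot beverage
🍃	leaf fluttering in wind
🌿	herb
🌱	seedling
🌈	rainbow
⚡	high voltage
💀	skull
☠	skull and crossbones
🤘	sign of the horns
🛒	shopping cart
💰	money bag
💵	dollar banknote
🏷	label
📦	package
🚚	delivery truck
📲	mobile phone with arrow
🔗	link
👀	eyes
💥	collision
🌬	wind face
🚭	no smoking
🔞	no one under eighteen
⚠	warning
❗	exclamation mark
❕	white exclamation mark
⭐	star
🌟	glowing star
🎉	party popper
🎁	wrapped gift
🆕	NEW button
🆓	FREE button
🔝	TOP arrow
➡	right arrow
⬇	down arrow
👇	backhand index pointing down
👉	backhand index pointing right
😏	smirking face
😁	beaming face with smiling eyes
😉	winking face
🥰	smiling face with hearts
😈	smiling face with horns
🤩	star-struck
😮‍💨	face exhaling
🚬	cigarette
💣	bomb
🧊	ice
❄	snowflake
🌊	water wave
☁	cloud
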