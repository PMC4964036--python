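item_code,label,domain,chart_order,adapted,culture_specific
PS1,Regard face,PS,1,false,false
PS2,Smile responsively,PS,2,false,false
PS3,Smile spontaneously,PS,3,false,false
PS4,Regard own hand,PS,4,false,false
PS5,Work for toy,PS,5,true,true
PS6,Feed self,PS,6,true,true
PS7,Play clapping game,PS,7,true,true
PS8,Indicate wants,PS,8,false,false
PS9,Wave bye-bye/Say good-bye,PS,9,true,true
PS10,Play ball with examiner,PS,10,false,true
PS11,Imitate activities,PS,11,true,true
PS12,Drink from cup or glass,PS,12,true,true
PS13,Help in house,PS,13,false,true
PS14,Eats using spoon/fork/fingers,PS,14,true,true
PS15,Remove garment,PS,15,true,true
PS16,Feed doll,PS,16,true,true
PS17,Put on clothing,PS,17,true,true
PS18,Wash mouth with help,PS,18,true,true
PS19,Wash and dry hands,PS,19,true,true
PS20,Name playmate,PS,20,true,true
PS21,Put on t-shirt,PS,21,true,true
PS22,"Dress, no help",PS,22,true,true
PS23,Play social games,PS,23,true,true
PS24,"Clean face, no help",PS,24,true,true
PS25,Serve oneself injera,PS,25,true,true
PS26,Toilet-going,PS,26,false,false
FM1,Follow to midline,FM,1,false,false
FM2,Follow past midline,FM,2,false,false
FM3,Grasp rattle,FM,3,false,false
FM4,Hands together,FM,4,false,false
FM5,Follow 180 degrees,FM,5,false,false
FM6,Regard coffee bean,FM,6,true,true
FM7,Reaches,FM,7,false,false
FM8,Look for yarn,FM,8,false,false
FM9,Rake coffee bean,FM,9,true,true
FM10,Pass cube,FM,10,false,false
FM11,Take 2 cubes,FM,11,false,false
FM12,Thumb-finger grasp,FM,12,true,true
FM13,Bang 2 cubes held in hands,FM,13,false,true
FM14,Put block in cup,FM,14,false,true
FM15,Scribbles,FM,15,true,true
FM16,"Dump coffee bean, demonstrated",FM,16,true,true
FM17,Tower of 2 cubes,FM,17,false,true
FM18,Tower of 4 cubes,FM,18,false,true
FM19,Tower of 6 cubes,FM,19,false,true
FM20,Imitate vertical line,FM,20,false,false
FM21,Tower of 8 cubes,FM,21,false,true
FM22,Thumb wiggle,FM,22,false,false
FM23,Copy O,FM,23,true,true
FM24,Draw person - 3 parts,FM,24,true,true
FM25,Copy +,FM,25,true,true
FM26,Pick longer line,FM,26,false,true
FM27,Copy square demonstrated,FM,27,false,true
FM28,Draw person - 6 parts,FM,28,true,true
FM29,Copy square,FM,29,true,true
LA1,Respond to bell,LA,1,false,false
LA2,Vocalizes,LA,2,false,false
LA3,Ooo/Aah,LA,3,false,false
LA4,Laugh,LA,4,false,false
LA5,Squeals,LA,5,false,false
LA6,Turn to rattling sound,LA,6,false,false
LA7,Turn to voice,LA,7,false,false
LA8,Single syllables,LA,8,false,false
LA9,Imitate speech sounds,LA,9,false,false
LA10,"Dada/Baba/Mama, non-specific",LA,10,false,false
LA11,Combine syllables,LA,11,false,false
LA12,Jabbers,LA,12,false,false
LA13,"Dada/Mama/baba, specific",LA,13,false,false
LA14,One word,LA,14,false,false
LA15,2 words,LA,15,false,false
LA16,3 words,LA,16,false,false
LA17,6 words,LA,17,false,false
LA18,Point 2 pictures,LA,18,false,true
LA19,Combine words,LA,19,false,false
LA20,Name 1 picture,LA,20,false,true
LA21,Body parts 6,LA,21,true,true
LA22,Point 4 pictures,LA,22,false,true
LA23,"Speech, half understandable",LA,23,false,false
LA24,Name 4 pictures,LA,24,false,true
LA25,Know 2 actions,LA,25,false,true
LA26,Know 2 adjectives,LA,26,false,true
LA27,Name 1 color,LA,27,true,true
LA28,Use of 2 objects,LA,28,true,true
LA29,Count 1 block,LA,29,false,true
LA30,Use of 3 objects,LA,30,true,true
LA31,Know 4 actions,LA,31,false,false
LA32,Speech all understandable,LA,32,false,false
LA33,Understand 4 prepositions,LA,33,false,false
LA34,Name 4 colors,LA,34,true,true
LA35,Define 5 words,LA,35,true,true
LA36,Know 3 adjectives,LA,36,false,false
LA37,Count 5 blocks,LA,37,true,true
LA38,Opposites-2,LA,38,false,false
LA39,Define 7 words,LA,39,true,true
GM1,Equal movement,GM,1,false,false
GM2,Lift head,GM,2,false,false
GM3,Head up 45 degrees,GM,3,false,false
GM4,Head up 90 degrees,GM,4,false,false
GM5,Sit head steady,GM,5,false,false
GM6,Bear weight on legs,GM,6,false,false
GM7,Chest up-arm support,GM,7,false,false
GM8,Roll over,GM,8,false,false
GM9,"Pull to sit, no head lag",GM,9,false,false
GM10,"Sit, no support",GM,10,false,false
GM11,"Stand, holding on",GM,11,false,false
GM12,Pull to stand,GM,12,false,false
GM13,Get to sitting,GM,13,false,false
GM14,Stand 2 s,GM,14,false,false
GM15,Stand alone,GM,15,false,false
GM16,Stoop and recover,GM,16,false,false
GM17,Walk well,GM,17,false,false
GM18,Walk backwards,GM,18,false,false
GM19,Runs,GM,19,false,false
GM20,Walk up steps,GM,20,false,true
GM21,Kick ball forward,GM,21,false,false
GM22,Jump up,GM,22,false,true
GM23,Throw ball overhand,GM,23,false,false
GM24,Broad jump,GM,24,false,false
GM25,Balance each foot 1 s,GM,25,false,false
GM26,Balance each foot 2 s,GM,26,false,false
GM27,Hops,GM,27,false,false
GM28,Balance each foot 3 s,GM,28,false,false
GM29,Balance each foot 4 s,GM,29,false,false
GM30,Balance each foot 5 s,GM,30,false,false
GM31,Heel-to-toe walk,GM,31,false,false
GM32,Balance each foot 6 s,GM,32,false,false
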