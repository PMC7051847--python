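item_number,domain,label,statement_0,statement_1
1,Authority,A1,I am not good at influencing people,I have a natural talent for influencing people
2,Exhibitionism,Exh2,I am essentially a modest person,Modesty does not become me
3,Exhibitionism,Exh3,I tend to be a fairly cautious person,I would do almost anything on a dare
4,Superiority,S4,When people compliment me I sometimes get embarrassed,I know that I am good because everybody keeps telling me so
5,Entitlement,En5,The thought of ruling the world frightens the hell out of me,If I ruled the world it would be a better place
6,Exploitativeness,Exp6,I try to accept the consequences of my behavior,I can usually talk my way out of anything
7,Exhibitionism,Exh7,I prefer to blend in with the crowd,I like to be the center of attention
8,Authority,A8,I am not too concerned about success,I will be a success
9,Superiority,S9,I am no better or worse than most people,I think I am a special person
10,Authority,A10,I am not sure if I would make a good leader,I see myself as a good leader
11,Authority,A11,I wish I were more assertive,I am assertive
12,Authority,A12,I do not mind following orders,I like to have authority over other people
13,Exploitativeness,Exp13,I do not like it when I find myself manipulating other people,I find it easy to manipulate people
14,Entitlement,En14,I usually get the respect that I deserve,I insist upon getting the respect that is due me
15,Vanity,V15,I do not particularly like to show off my body,I like to show off my body
16,Exploitativeness,Exp16,People are sometimes hard to understand,I can read people like a book
17,Self-sufficiency,SS17,"If I feel competent, I am willing to take responsibility for making decisions",I like to take responsibility for making decisions
18,Entitlement,En18,I just want to be reasonably happy,I want to amount to something in the eyes of the world
19,Vanity,V19,My body is nothing special,I like to look at my body
20,Exhibitionism,Exh20,I try not to be a show off,I will usually show off if I get the chance
21,Self-sufficiency,SS21,Sometimes I am not sure of what I am doing,I always know what I am doing
22,Self-sufficiency,SS22,I sometimes depend on people to get things done,I rarely depend on anyone else to get things done
23,Exploitativeness,Exp23,Sometimes I tell good stories,Everybody likes to hear my stories
24,Entitlement,En24,I like to do things for other people,I expect a great deal from other people
25,Entitlement,En25,I take my satisfactions as they come,I will never be satisfied until I get all that I deserve
26,Superiority,S26,Compliments embarrass me,I like to be complimented
27,Entitlement,En27,Power for its own sake does not interest me,I have a strong will to power
28,Exhibitionism,Exh28,I do not care about new fads and fashions,I like to start new fads and fashion
29,Vanity,V29,I am not particularly interested in looking at myself,I like to look myself in the mirror
30,Exhibitionism,Exh30,It makes me uncomfortable to be the center of attention,I really like to be the center of attention
31,Self-sufficiency,SS31,People cannot always live their lives in term of what they want.,I can live my life in any way I want to
32,Authority,A32,Being an authority does not mean that much to me,People always seem to recognize my authority
33,Authority,A33,It makes little difference to me whether I am a leader or not,I would prefer to be a leader
34,Self-sufficiency,SS34,I hope I am going to be successful,I am going to be a great person
35,Exploitativeness,Exp35,People sometimes believe what I tell them,I can make anybody believe anything I want them to
36,Authority,A36,Leadership is a quality that takes a long time to develop,I am a born leader
37,Superiority,S37,I do not like people to pry into my life for any reason,I wish somebody would someday write my biography
38,Exhibitionism,Exh38,I do not mind blending into the crowd when I go out in public,I get upset when people do not notice how I look when I go out in public
39,Self-sufficiency,SS39,There is a lot that I can learn from other people,I am more capable than other people
40,Superiority,S40,I am much like everybody else,I am an extraordinary person
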