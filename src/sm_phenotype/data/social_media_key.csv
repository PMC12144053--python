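# social-media app category key, schema=1 (2020 study-period categorization; re-categorize periodically as app functionality evolves)
app_label,package_name,sns,broad,google_play,popular
ACM,com.narvii.amino.manager,1,1,1,0
Amino,com.narvii.amino.master,1,1,1,0
BIGO LIVE,sg.bigo.live,1,1,1,0
byte,co.byte,1,1,1,0
Facebook,com.facebook.katana,1,1,1,1
Hoop,com.dazz.hoop,1,1,1,0
Instagram,com.instagram.android,1,1,1,1
Litmatch,com.litatom.app,1,1,1,0
LMK,com.lightspace.lmk,1,1,1,0
Peanut,com.teampeanut.peanut,1,1,1,0
Quack,com.quack.app,1,1,1,0
Reddit,com.reddit.frontpage,1,1,1,1
Snapchat,com.snapchat.android,1,1,1,1
TikTok,com.zhiliaoapp.musically,1,1,1,1
Tumblr,com.tumblr,1,1,1,0
Twitter,com.twitter.android,1,1,0,1
Discord,com.discord,1,1,0,1
Quora,com.quora.android,1,1,0,0
rif is fun,com.andrewshu.android.reddit,1,1,0,0
YouTube,com.google.android.youtube,1,1,0,1
Joi,video.chat.joi,0,1,1,0
Monkey,cool.monkey.android,0,1,1,0
Pinterest,com.pinterest,0,1,1,0
Plink,tech.plink.PlinkApp,0,1,1,0
Weverse,co.benx.weverse,0,1,1,0
Wink,co.ninecount.wink,0,1,1,0
YOLO,com.popshow.yolo,0,1,1,0
Yubo,co.yellw.yellowapp,0,1,1,0
iFunny,mobi.ifunny,0,1,0,0
Likee,video.like,0,1,0,0
LMKpoll,com.rubysparklabs.lmk,0,1,0,0
Omegle,com.ni.Omegle,0,1,0,0
sendit,com.fullsenders.sendit,0,1,0,0
Spotafriend,com.mylol.spotafriend,0,1,0,0
Steam,com.valvesoftware.android.steam.community,0,1,0,0
StoryFire,com.storyfire.storyfire,0,1,0,0
Tinder,com.tinder,0,1,0,0
Twitch,tv.twitch.android.app,0,1,0,1
Vimeo,com.vimeo.android.videoapp,0,1,0,0
Vine Camera,co.vine.android,0,1,0,0
Wattpad,wp.wattpad,0,1,0,0
Airtime,com.signal.android,0,0,1,0
BAND,com.nhn.android.band,0,0,1,0
Houseparty,com.herzick.houseparty,0,0,1,0
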